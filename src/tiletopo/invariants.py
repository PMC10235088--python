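"""Knot invariants computed from planar diagrams.

The identification instrument is the Alexander polynomial (cheap: a
determinant of the Fox-calculus relation matrix of the Wirtinger
presentation) plus the Jones polynomial via the Kauffman bracket state sum
(exponential, used on small diagrams to resolve chirality).  Laurent
polynomials over the integers are the common currency.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import product

from .diagrams import Diagram

__all__ = [
    "LaurentPolynomial",
    "alexander_polynomial",
    "kauffman_bracket",
    "jones_polynomial",
    "BracketCapExceeded",
]


@dataclass(frozen=True)
class LaurentPolynomial:
    """An integer Laurent polynomial, stored as sorted (exponent, coeff)."""

    terms: tuple[tuple[int, int], ...]

    # -- construction ------------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict[int, int]) -> "LaurentPolynomial":
        return cls(tuple(sorted((e, c) for e, c in d.items() if c != 0)))

    @classmethod
    def zero(cls) -> "LaurentPolynomial":
        return cls(())

    @classmethod
    def one(cls) -> "LaurentPolynomial":
        return cls(((0, 1),))

    @classmethod
    def monomial(cls, exponent: int, coeff: int = 1) -> "LaurentPolynomial":
        return cls.from_dict({exponent: coeff})

    def as_dict(self) -> dict[int, int]:
        return dict(self.terms)

    # -- ring operations ---------------------------------------------------
    def __add__(self, other: "LaurentPolynomial") -> "LaurentPolynomial":
        d = self.as_dict()
        for e, c in other.terms:
            d[e] = d.get(e, 0) + c
        return LaurentPolynomial.from_dict(d)

    def __neg__(self) -> "LaurentPolynomial":
        return LaurentPolynomial(tuple((e, -c) for e, c in self.terms))

    def __sub__(self, other: "LaurentPolynomial") -> "LaurentPolynomial":
        return self + (-other)

    def __mul__(self, other: "LaurentPolynomial") -> "LaurentPolynomial":
        d: dict[int, int] = {}
        for e1, c1 in self.terms:
            for e2, c2 in other.terms:
                e = e1 + e2
                d[e] = d.get(e, 0) + c1 * c2
        return LaurentPolynomial.from_dict(d)

    def shift(self, k: int) -> "LaurentPolynomial":
        return LaurentPolynomial(tuple((e + k, c) for e, c in self.terms))

    # -- queries -----------------------------------------------------------
    @property
    def is_zero(self) -> bool:
        return not self.terms

    @property
    def min_exp(self) -> int:
        return self.terms[0][0]

    @property
    def max_exp(self) -> int:
        return self.terms[-1][0]

    def __call__(self, x: Fraction | int) -> Fraction | int:
        return sum(c * x**e for e, c in self.terms)

    # -- knot-theory conveniences -----------------------------------------
    def mirror(self) -> "LaurentPolynomial":
        """Substitute t -> 1/t (the Jones mirror rule)."""
        return LaurentPolynomial(tuple(sorted((-e, c) for e, c in self.terms)))

    def normalize_alexander(self) -> "LaurentPolynomial":
        """Multiply by a unit so the minimum exponent is 0 and the
        lowest-degree coefficient is positive."""
        if self.is_zero:
            return self
        p = self.shift(-self.min_exp)
        if p.terms[0][1] < 0:
            p = -p
        return p

    def determinant(self) -> int:
        """|Delta(-1)|, the knot determinant checksum."""
        return abs(self(-1))

    def divide_exact(self, other: "LaurentPolynomial"):
        """Exact quotient in Z[t] of the normalized polynomials, or None.

        Both operands are Alexander-normalized first; the quotient is
        returned normalized as well.
        """
        b = other.normalize_alexander()
        if b.is_zero:
            return None
        a = self.normalize_alexander().as_dict()
        deg_b = b.max_exp
        lead_b = b.as_dict()[deg_b]
        q: dict[int, int] = {}
        while a:
            deg_a = max(a)
            if deg_a < deg_b:
                return None
            lead_a = a[deg_a]
            if lead_a % lead_b != 0:
                return None
            coeff = lead_a // lead_b
            q[deg_a - deg_b] = coeff
            for e, c in b.terms:
                k = e + deg_a - deg_b
                a[k] = a.get(k, 0) - coeff * c
                if a[k] == 0:
                    del a[k]
        return LaurentPolynomial.from_dict(q).normalize_alexander()

    def __str__(self) -> str:
        if self.is_zero:
            return "0"
        parts = []
        for e, c in self.terms:
            if e == 0:
                parts.append(f"{c:+d}")
            elif e == 1:
                parts.append(f"{c:+d}*t")
            else:
                parts.append(f"{c:+d}*t^{e}")
        s = " ".join(parts)
        return s[1:] if s.startswith("+") else s


# --------------------------------------------------------------------------
# Alexander polynomial


def _bareiss_det(m: list[list[int]]) -> int:
    """Fraction-free Bareiss determinant of an integer matrix."""
    n = len(m)
    if n == 0:
        return 1
    m = [row[:] for row in m]
    sign = 1
    prev = 1
    for k in range(n - 1):
        if m[k][k] == 0:
            for i in range(k + 1, n):
                if m[i][k] != 0:
                    m[k], m[i] = m[i], m[k]
                    sign = -sign
                    break
            else:
                return 0
        for i in range(k + 1, n):
            for j in range(k + 1, n):
                m[i][j] = (m[i][j] * m[k][k] - m[i][k] * m[k][j]) // prev
            m[i][k] = 0
        prev = m[k][k]
    return sign * m[n - 1][n - 1]


def _interpolate(xs: list[int], ys: list[int]) -> LaurentPolynomial:
    """Exact Lagrange interpolation; the result must be integral."""
    n = len(xs)
    coeffs = [Fraction(0)] * n
    for i in range(n):
        # basis polynomial for xs[i]
        basis = [Fraction(1)]
        denom = Fraction(1)
        for j in range(n):
            if j == i:
                continue
            new = [Fraction(0)] * (len(basis) + 1)
            for k, c in enumerate(basis):
                new[k] -= c * xs[j]
                new[k + 1] += c
            basis = new
            denom *= xs[i] - xs[j]
        scale = Fraction(ys[i]) / denom
        for k, c in enumerate(basis):
            coeffs[k] += c * scale
    out: dict[int, int] = {}
    for k, c in enumerate(coeffs):
        if c != 0:
            assert c.denominator == 1, "interpolation must be integral"
            out[k] = int(c)
    return LaurentPolynomial.from_dict(out)


def alexander_polynomial(d: Diagram) -> LaurentPolynomial:
    """Normalized Alexander polynomial of a single-component diagram.

    Built from the Wirtinger presentation: one generator per over-arc, one
    Fox-derivative relation row per crossing; delete one column and take
    the determinant.  The determinant (degree < n in t) is computed by
    evaluating at n+1 integer points with exact Bareiss elimination and
    interpolating, which avoids symbolic matrix arithmetic.
    """
    n = d.n_crossings
    if n == 0:
        return LaurentPolynomial.one()

    # Merge PD edges into over-arcs: over passages do not break an arc.
    parent = list(range(2 * n + 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        parent[find(x)] = find(y)

    for c in d.crossings:
        a, b, cc, dd = c.arcs
        over_in, over_out = (dd, b) if c.sign > 0 else (b, dd)
        union(over_in, over_out)

    classes = sorted({find(i) for i in range(1, 2 * n + 1)})
    col = {root: i for i, root in enumerate(classes)}
    if len(classes) != n:  # pragma: no cover - sanity
        raise AssertionError("over-arc count must equal crossing count")

    def rows_at(t: int) -> list[list[int]]:
        m = [[0] * n for _ in range(n)]
        for i, c in enumerate(d.crossings):
            a, b, cc, dd = c.arcs
            over = col[find(dd if c.sign > 0 else b)]
            u_in, u_out = col[find(a)], col[find(cc)]
            if c.sign > 0:
                m[i][over] += 1 - t
                m[i][u_in] += t
                m[i][u_out] += -1
            else:
                m[i][over] += t - 1
                m[i][u_in] += 1
                m[i][u_out] += -t
        return [row[: n - 1] for row in m[: n - 1]] if n > 1 else [[]]

    if n == 1:
        return LaurentPolynomial.one()
    xs = list(range(2, 2 + n))
    ys = [_bareiss_det([row[:] for row in rows_at(x)]) for x in xs]
    poly = _interpolate(xs, ys)
    if poly.is_zero:  # pragma: no cover - cannot happen for a knot
        raise AssertionError("vanishing Alexander determinant on a knot")
    return poly.normalize_alexander()


# --------------------------------------------------------------------------
# Kauffman bracket and Jones polynomial


class BracketCapExceeded(RuntimeError):
    """State sum too large; use the symbolic engine instead."""


def kauffman_bracket(d: Diagram, cap: int = 24) -> LaurentPolynomial:
    """Kauffman bracket by brute-force state sum in the bracket variable A.

    Sums over all 2^n smoothings; each state contributes
    A^(#A - #B) * (-A^2 - A^-2)^(loops - 1).
    """
    n = d.n_crossings
    if n > cap:
        raise BracketCapExceeded(
            f"{n} crossings exceeds the bracket cap of {cap}"
        )
    if n == 0:
        return LaurentPolynomial.one()

    # Per crossing, the two smoothing pairings in terms of PD arc labels
    # (a, b, c, d) counterclockwise from the under-in arc; the over strand
    # occupies positions b and d.  Rotating the over strand counterclockwise
    # onto the under strand sweeps the A regions: the A smoothing joins
    # (a, b) and (c, d), the B smoothing joins (b, c) and (d, a).  The
    # one-crossing kink diagram pins this orientation of the rule.
    a_pairs = []
    b_pairs = []
    for c in d.crossings:
        a, b, cc, dd = c.arcs
        a_pairs.append(((a, b), (cc, dd)))
        b_pairs.append(((b, cc), (dd, a)))

    delta = LaurentPolynomial.from_dict({2: -1, -2: -1})
    # delta powers cache
    deltas = [LaurentPolynomial.one()]
    for _ in range(n + 1):
        deltas.append(deltas[-1] * delta)

    total: dict[int, int] = {}
    edges = 2 * n
    for state in product((0, 1), repeat=n):
        parent = list(range(edges + 1))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, s in enumerate(state):
            for x, y in (a_pairs[i] if s == 0 else b_pairs[i]):
                parent[find(x)] = find(y)
        loops = len({find(i) for i in range(1, edges + 1)})
        n_b = sum(state)
        exp = n - 2 * n_b  # (#A - #B)
        for e, coeff in deltas[loops - 1].terms:
            total[e + exp] = total.get(e + exp, 0) + coeff
    return LaurentPolynomial.from_dict(total)


def jones_polynomial(d: Diagram, cap: int = 24) -> LaurentPolynomial:
    """Jones polynomial V(t): writhe-normalized bracket at A = t^(-1/4).

    Distinguishes mirror images whenever the polynomial is non-palindromic:
    the mirror diagram yields the variable-inverted polynomial.
    """
    bracket = kauffman_bracket(d, cap=cap)
    w = d.writhe()
    # f = (-A^3)^(-w) * bracket = (-1)^w A^(-3w) * bracket
    shifted = bracket.shift(-3 * w)
    if w % 2:
        shifted = -shifted
    out: dict[int, int] = {}
    for e, c in shifted.terms:
        q, r = divmod(-e, 4)
        if r:
            raise AssertionError(
                "bracket exponents of a knot must be multiples of 4 after "
                "writhe normalization"
            )
        out[q] = c
    return LaurentPolynomial.from_dict(out)
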