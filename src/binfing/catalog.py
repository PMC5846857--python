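"""Catalog of binary similarity coefficients for presence/absence fingerprints.

Every coefficient is a function of the 2x2 contingency counts between two
bit-vectors: ``a`` (1-1 matches), ``b`` (1-0), ``c`` (0-1), ``d`` (0-0) and
``p = a + b + c + d`` (fingerprint length).  The catalog follows the taxonomy
of Todeschini, Consonni, Xiang, Holliday, Willett & Maggiora (2012,
J. Chem. Inf. Model. 52:2884), which groups coefficients by *concordance
symmetry* — how the 0-0 count ``d`` is weighted relative to ``a``:

* ``S`` (symmetric): d counts equally with a,
* ``A`` (asymmetric): d is ignored,
* ``I`` (intermediate): d is down-weighted,
* ``Q`` (correlation-based): coefficients on a correlation-like scale that
  need an affine map onto [0, 1],

and by *metricity* — whether the induced dissimilarity ``1 - s'`` satisfies
the metric axioms.  Metricity tags shipped here are verified by exhaustive
brute force over bit-vector triples (see the test suite), with identity of
indiscernibles relaxed for coefficients whose self-similarity is not maximal
(e.g. Russell-Rao).

Raw coefficient values are mapped onto [0, 1] by ``s' = (s + alpha) / beta``.
For coefficients whose raw range depends on the fingerprint length, ``alpha``
and ``beta`` are functions of ``p``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ContingencyCounts",
    "MeasureSpec",
    "contingency",
    "catalog",
    "get_measure",
    "evaluate_raw",
    "rescale",
    "evaluate",
    "catalog_frame",
]

CLASS_NAMES = {
    "S": "symmetric",
    "A": "asymmetric",
    "I": "intermediate",
    "Q": "correlation-based",
}
METRICITY_NAMES = {"M": "metric", "N": "non-metric"}


@dataclass(frozen=True)
class ContingencyCounts:
    """Contingency counts between two equal-length bit-vectors."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"contingency count {name!r} must be a non-negative integer, got {v}")

    @property
    def p(self) -> int:
        """Total number of features (fingerprint length)."""
        return self.a + self.b + self.c + self.d

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (self.a, self.b, self.c, self.d, self.p)


def _as_bits(v, name: str) -> np.ndarray:
    arr = np.asarray(v)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} contains non-binary entries: {vals[~np.isin(vals, (0, 1))]!r}")
    return arr.astype(np.int64)


def contingency(x: Sequence[int], y: Sequence[int]) -> ContingencyCounts:
    """Count 1-1, 1-0, 0-1 and 0-0 positions between bit-vectors *x* and *y*."""
    xb = _as_bits(x, "x")
    yb = _as_bits(y, "y")
    if xb.shape != yb.shape:
        raise ValueError(f"length mismatch: {xb.shape[0]} vs {yb.shape[0]}")
    a = int(np.sum((xb == 1) & (yb == 1)))
    b = int(np.sum((xb == 1) & (yb == 0)))
    c = int(np.sum((xb == 0) & (yb == 1)))
    d = int(np.sum((xb == 0) & (yb == 0)))
    return ContingencyCounts(a, b, c, d)


class _Guard:
    """Division guard: records cells with a zero denominator.

    Degenerate cells get a placeholder 0; :func:`evaluate_raw` afterwards
    overwrites every flagged cell with the catalog convention (maximal raw
    value when the fingerprints are identical, neutral 0 otherwise).
    """

    def __init__(self, shape) -> None:
        self.flag = np.zeros(shape, dtype=bool)

    def __call__(self, num, den):
        num = np.asarray(num, dtype=float)
        den = np.asarray(den, dtype=float)
        bad = den == 0
        self.flag |= bad
        return np.where(bad, 0.0, num) / np.where(bad, 1.0, den)


@dataclass(frozen=True)
class MeasureSpec:
    """One binary similarity coefficient.

    ``formula`` is a plain-text expression in a, b, c, d, p that an
    independent evaluator can parse (used as an oracle in the tests);
    ``alpha``/``beta`` are the [0,1] rescaling constants as functions of p.
    """

    id: str
    full_name: str
    class_tag: str  # S / A / I / Q
    metricity_tag: str  # M / N
    formula: str
    scaling: str  # display form of the rescaling constants
    citation: str
    self_maximal: bool  # s(x, x) attains the coefficient's maximum
    order_dependent: bool = False  # value changes when the two vectors swap
    metric_transform: str | None = None  # distance transform verified metric ("1-s" or "sqrt(1-s)")
    alpha: Callable[[np.ndarray], np.ndarray] = field(default=lambda p: 0.0, repr=False, compare=False)
    beta: Callable[[np.ndarray], np.ndarray] = field(default=lambda p: 1.0, repr=False, compare=False)
    _fn: Callable = field(default=None, repr=False, compare=False)

    @property
    def class_name(self) -> str:
        return CLASS_NAMES[self.class_tag]

    @property
    def metricity_name(self) -> str:
        return METRICITY_NAMES[self.metricity_tag]


# ---------------------------------------------------------------------------
# Raw formulas.  F is the guarded division; all arguments are float arrays.
# Citations point at the primary sources / the Todeschini et al. compilation.
# ---------------------------------------------------------------------------

def _sm(a, b, c, d, p, F):
    return F(a + d, p)


def _rt(a, b, c, d, p, F):
    return F(a + d, p + b + c)


def _jt(a, b, c, d, p, F):
    return F(a, a + b + c)


def _gle(a, b, c, d, p, F):
    return F(2 * a, 2 * a + b + c)


def _rr(a, b, c, d, p, F):
    return F(a, p)


def _forbes(a, b, c, d, p, F):
    return F(a * p, (a + b) * (a + c))


def _sim(a, b, c, d, p, F):
    return F(a, np.minimum(a + b, a + c))


def _bb(a, b, c, d, p, F):
    return F(a, np.maximum(a + b, a + c))


def _dk(a, b, c, d, p, F):
    return F(a, np.sqrt((a + b) * (a + c)))


def _bub(a, b, c, d, p, F):
    r = np.sqrt(a * d)
    return F(r + a, r + a + b + c)


def _kul(a, b, c, d, p, F):
    return F(a, b + c)


def _ss1(a, b, c, d, p, F):
    return F(a, a + 2 * (b + c))


def _ss2(a, b, c, d, p, F):
    return F(2 * (a + d), p + a + d)


def _ss3(a, b, c, d, p, F):
    return 0.25 * (F(a, a + b) + F(a, a + c) + F(d, b + d) + F(d, c + d))


def _ss4(a, b, c, d, p, F):
    return F(a * d, np.sqrt((a + b) * (a + c) * (b + d) * (c + d)))


def _ja(a, b, c, d, p, F):
    return F(3 * a, 3 * a + b + c)


def _fai(a, b, c, d, p, F):
    return F(a + 0.5 * d, p)


def _mou(a, b, c, d, p, F):
    return F(2 * a, a * (b + c) + 2 * b * c)


def _mic(a, b, c, d, p, F):
    return F(4 * (a * d - b * c), (a + d) ** 2 + (b + c) ** 2)


def _rg(a, b, c, d, p, F):
    return F(a, 2 * a + b + c) + F(d, 2 * d + b + c)


def _hd(a, b, c, d, p, F):
    return 0.5 * (F(a, a + b + c) + F(d, b + c + d))


def _yu(a, b, c, d, p, F):
    return F(a * d - b * c, a * d + b * c)


def _yu2(a, b, c, d, p, F):
    r, s = np.sqrt(a * d), np.sqrt(b * c)
    return F(r - s, r + s)


def _fos(a, b, c, d, p, F):
    return F(p * (a - 0.5) ** 2, (a + b) * (a + c))


def _den(a, b, c, d, p, F):
    return F(a * d - b * c, np.sqrt(p * (a + b) * (a + c)))


def _gow(a, b, c, d, p, F):
    return F(a + d, np.sqrt((a + b) * (a + c) * (b + d) * (c + d)))


def _gl(a, b, c, d, p, F):
    return F(a + d, a + d + 0.5 * (b + c))


def _dis(a, b, c, d, p, F):
    return F(a * d - b * c, p * p)


def _gk(a, b, c, d, p, F):
    m = np.minimum(a, d)
    return F(2 * m - b - c, 2 * m + b + c)


def _phi(a, b, c, d, p, F):
    return F(a * d - b * c, np.sqrt((a + b) * (a + c) * (b + d) * (c + d)))


def _di1(a, b, c, d, p, F):
    return F(a, a + b)


def _di2(a, b, c, d, p, F):
    return F(a, a + c)


def _sor(a, b, c, d, p, F):
    return F(a * a, (a + b) * (a + c))


def _coh(a, b, c, d, p, F):
    return F(2 * (a * d - b * c), (a + b) * (b + d) + (a + c) * (c + d))


def _pe1(a, b, c, d, p, F):
    return F(a * d - b * c, (a + b) * (c + d))


def _pe2(a, b, c, d, p, F):
    return F(a * d - b * c, (a + c) * (b + d))


def _mp(a, b, c, d, p, F):
    return F(2 * (a * d - b * c), (a + b) * (c + d) + (a + c) * (b + d))


def _hl(a, b, c, d, p, F):
    return F(a * (2 * d + b + c), 2 * (a + b + c)) + F(d * (2 * a + b + c), 2 * (b + c + d))


def _ac(a, b, c, d, p, F):
    return (2.0 / np.pi) * np.arcsin(np.sqrt(F(a + d, p)))


def _ct1(a, b, c, d, p, F):
    return F(np.log1p(a + d), np.log1p(p))


def _ct2(a, b, c, d, p, F):
    return F(np.log1p(p) - np.log1p(b + c), np.log1p(p))


def _ct3(a, b, c, d, p, F):
    return F(np.log1p(a), np.log1p(p))


def _ct4(a, b, c, d, p, F):
    return F(np.log1p(a), np.log1p(a + b + c))


def _ct5(a, b, c, d, p, F):
    return F(np.log1p(a * d) - np.log1p(b * c), np.log1p(p * p / 4.0))


# p-dependent scaling helpers
def _zero(p):
    return np.zeros_like(np.asarray(p, dtype=float))


def _one(p):
    return np.ones_like(np.asarray(p, dtype=float))


def _two(p):
    return 2.0 * np.ones_like(np.asarray(p, dtype=float))


def _p(p):
    return np.asarray(p, dtype=float)


def _p_minus_1(p):
    return np.maximum(np.asarray(p, dtype=float) - 1.0, 1.0)


def _fos_beta(p):
    p = np.asarray(p, dtype=float)
    return (p - 0.5) ** 2 / p


def _gow_beta(p):
    p = np.asarray(p, dtype=float)
    return p / np.maximum(p - 1.0, 1.0)


def _den_alpha(p):
    return np.sqrt(np.asarray(p, dtype=float)) / 2.0


def _den_beta(p):
    p = np.asarray(p, dtype=float)
    return (3.0 * p - 2.0) / (2.0 * np.sqrt(p))


def _quarter(p):
    return 0.25 * np.ones_like(np.asarray(p, dtype=float))


def _half(p):
    return 0.5 * np.ones_like(np.asarray(p, dtype=float))


def _m(
    mid, name, cls, met, formula, fn, citation, self_maximal,
    alpha=_zero, beta=_one, scaling=None, order_dependent=False, transform=None,
) -> MeasureSpec:
    if scaling is None:
        scaling = {_zero: "alpha=0, beta=1", _one: "alpha=1, beta=2"}.get(alpha, "")
        if alpha is _zero and beta is _one:
            scaling = "alpha=0, beta=1"
        elif alpha is _one and beta is _two:
            scaling = "alpha=1, beta=2"
    return MeasureSpec(
        id=mid, full_name=name, class_tag=cls, metricity_tag=met, formula=formula,
        scaling=scaling, citation=citation, self_maximal=self_maximal,
        order_dependent=order_dependent, metric_transform=transform,
        alpha=alpha, beta=beta, _fn=fn,
    )


# Metricity tags below are the brute-force-verified ones (triangle inequality
# of 1 - s' over all bit-vector triples up to length 5, with the degenerate
# conventions applied); see tests/test_catalog.py.
_CATALOG: tuple[MeasureSpec, ...] = (
    # --- symmetric (S): d weighted like a -------------------------------
    _m("SM", "Sokal-Michener (simple matching)", "S", "M", "(a+d)/p", _sm,
       "Sokal & Michener 1958", True, transform="1-s"),
    _m("RT", "Rogers-Tanimoto", "S", "M", "(a+d)/(p+b+c)", _rt,
       "Rogers & Tanimoto 1960", True, transform="1-s"),
    _m("SS2", "Sokal-Sneath 2", "S", "M", "2*(a+d)/(p+a+d)", _ss2,
       "Sokal & Sneath 1963", True, transform="sqrt(1-s)"),
    _m("SS3", "Sokal-Sneath 3", "S", "M",
       "(a/(a+b)+a/(a+c)+d/(b+d)+d/(c+d))/4", _ss3, "Sokal & Sneath 1963", True,
       transform="sqrt(1-s)"),
    _m("SS4", "Sokal-Sneath 4 (Ochiai 2)", "S", "N",
       "a*d/sqrt((a+b)*(a+c)*(b+d)*(c+d))", _ss4, "Sokal & Sneath 1963", True),
    _m("RG", "Rogot-Goldberg", "S", "M", "a/(2*a+b+c)+d/(2*d+b+c)", _rg,
       "Rogot & Goldberg 1966", True, transform="sqrt(1-s)"),
    _m("HD", "Hawkins-Dotson", "S", "M", "(a/(a+b+c)+d/(b+c+d))/2", _hd,
       "Hawkins & Dotson 1975", True, transform="1-s"),
    _m("GL", "Gower-Legendre", "S", "M", "(a+d)/(a+d+(b+c)/2)", _gl,
       "Gower & Legendre 1986", True, transform="sqrt(1-s)"),
    _m("Gow", "Gower", "S", "M",
       "(a+d)/sqrt((a+b)*(a+c)*(b+d)*(c+d))", _gow, "Gower 1971", False,
       beta=_gow_beta, scaling="alpha=0, beta=p/(p-1)", transform="1-s"),
    _m("HL", "Harris-Lahey", "S", "N",
       "a*(2*d+b+c)/(2*(a+b+c))+d*(2*a+b+c)/(2*(b+c+d))", _hl,
       "Harris & Lahey 1978", True, beta=_p, scaling="alpha=0, beta=p"),
    _m("AC", "Austin-Colwell", "S", "M", "(2/pi)*asin(sqrt((a+d)/p))", _ac,
       "Austin & Colwell 1977", True, transform="1-s"),
    _m("CT1", "Consonni-Todeschini 1", "S", "M", "log(1+a+d)/log(1+p)", _ct1,
       "Consonni & Todeschini 2012", True, transform="sqrt(1-s)"),
    _m("CT2", "Consonni-Todeschini 2", "S", "M",
       "(log(1+p)-log(1+b+c))/log(1+p)", _ct2, "Consonni & Todeschini 2012", True,
       transform="1-s"),
    # --- asymmetric (A): d ignored --------------------------------------
    _m("JT", "Jaccard-Tanimoto", "A", "M", "a/(a+b+c)", _jt,
       "Jaccard 1901; Tanimoto 1957", True, transform="1-s"),
    _m("Gle", "Gleason (Dice-Sorensen)", "A", "N", "2*a/(2*a+b+c)", _gle,
       "Gleason 1920; Dice 1945", True),
    _m("RR", "Russell-Rao", "A", "M", "a/p", _rr,
       "Russell & Rao 1940", False, transform="1-s"),
    _m("For", "Forbes", "A", "M", "a*p/((a+b)*(a+c))", _forbes,
       "Forbes 1907", False, beta=_p, scaling="alpha=0, beta=p", transform="1-s"),
    _m("Sim", "Simpson", "A", "N", "a/min(a+b,a+c)", _sim,
       "Simpson 1943", True),
    _m("BB", "Braun-Blanquet", "A", "M", "a/max(a+b,a+c)", _bb,
       "Braun-Blanquet 1932", True, transform="1-s"),
    _m("DK", "Driver-Kroeber (Ochiai)", "A", "N", "a/sqrt((a+b)*(a+c))", _dk,
       "Driver & Kroeber 1932; Ochiai 1957", True),
    _m("Kul", "Kulczynski", "A", "N", "a/(b+c)", _kul,
       "Kulczynski 1927", True, beta=_p_minus_1, scaling="alpha=0, beta=p-1"),
    _m("SS1", "Sokal-Sneath 1", "A", "M", "a/(a+2*(b+c))", _ss1,
       "Sokal & Sneath 1963", True, transform="1-s"),
    _m("Ja", "3W-Jaccard", "A", "N", "3*a/(3*a+b+c)", _ja,
       "Jaccard 1901 (three-weighted variant)", True),
    _m("Sor", "Sorgenfrei", "A", "N", "a*a/((a+b)*(a+c))", _sor,
       "Sorgenfrei 1958", True),
    _m("Mou", "Mountford", "A", "N", "2*a/(a*(b+c)+2*b*c)", _mou,
       "Mountford 1962", True, beta=_two, scaling="alpha=0, beta=2"),
    _m("Fos", "Fossum", "A", "N", "p*(a-0.5)**2/((a+b)*(a+c))", _fos,
       "Fossum 1966", False, beta=_fos_beta, scaling="alpha=0, beta=(p-1/2)^2/p"),
    _m("Di1", "Dice 1 (Wallace)", "A", "N", "a/(a+b)", _di1,
       "Dice 1945; Wallace 1983", True, order_dependent=True),
    _m("Di2", "Dice 2 (Wallace)", "A", "N", "a/(a+c)", _di2,
       "Dice 1945; Wallace 1983", True, order_dependent=True),
    _m("CT3", "Consonni-Todeschini 3", "A", "M", "log(1+a)/log(1+p)", _ct3,
       "Consonni & Todeschini 2012", False, transform="sqrt(1-s)"),
    _m("CT4", "Consonni-Todeschini 4", "A", "M", "log(1+a)/log(1+a+b+c)", _ct4,
       "Consonni & Todeschini 2012", True, transform="sqrt(1-s)"),
    # --- intermediate (I): d down-weighted ------------------------------
    _m("BUB", "Baroni-Urbani-Buser", "I", "M",
       "(sqrt(a*d)+a)/(sqrt(a*d)+a+b+c)", _bub, "Baroni-Urbani & Buser 1976", True,
       transform="sqrt(1-s)"),
    _m("Fai", "Faith", "I", "M", "(a+d/2)/p", _fai,
       "Faith 1983", False, transform="1-s"),
    # --- correlation-based (Q): [-1, 1] scale ---------------------------
    _m("Yu", "Yule Q", "Q", "N", "(a*d-b*c)/(a*d+b*c)", _yu,
       "Yule 1900", True, alpha=_one, beta=_two, scaling="alpha=1, beta=2"),
    _m("Yu2", "Yule Y (omega)", "Q", "N",
       "(sqrt(a*d)-sqrt(b*c))/(sqrt(a*d)+sqrt(b*c))", _yu2,
       "Yule 1912", True, alpha=_one, beta=_two, scaling="alpha=1, beta=2"),
    _m("Phi", "Pearson phi", "Q", "N",
       "(a*d-b*c)/sqrt((a+b)*(a+c)*(b+d)*(c+d))", _phi,
       "Yule 1912; Pearson", True, alpha=_one, beta=_two, scaling="alpha=1, beta=2"),
    _m("Coh", "Cohen kappa", "Q", "M",
       "2*(a*d-b*c)/((a+b)*(b+d)+(a+c)*(c+d))", _coh,
       "Cohen 1960", True, alpha=_one, beta=_two, scaling="alpha=1, beta=2",
       transform="sqrt(1-s)"),
    _m("MP", "Maxwell-Pilliner", "Q", "M",
       "2*(a*d-b*c)/((a+b)*(c+d)+(a+c)*(b+d))", _mp,
       "Maxwell & Pilliner 1968", True, alpha=_one, beta=_two, scaling="alpha=1, beta=2",
       transform="sqrt(1-s)"),
    _m("Mic", "Michael", "Q", "N",
       "4*(a*d-b*c)/((a+d)**2+(b+c)**2)", _mic,
       "Michael 1920", False, alpha=_one, beta=_two, scaling="alpha=1, beta=2"),
    _m("Pe1", "Peirce 1", "Q", "N", "(a*d-b*c)/((a+b)*(c+d))", _pe1,
       "Peirce 1884", True, alpha=_one, beta=_two, scaling="alpha=1, beta=2",
       order_dependent=True),
    _m("Pe2", "Peirce 2", "Q", "N", "(a*d-b*c)/((a+c)*(b+d))", _pe2,
       "Peirce 1884", True, alpha=_one, beta=_two, scaling="alpha=1, beta=2",
       order_dependent=True),
    _m("GK", "Goodman-Kruskal lambda", "Q", "N",
       "(2*min(a,d)-b-c)/(2*min(a,d)+b+c)", _gk,
       "Goodman & Kruskal 1954", True, alpha=_one, beta=_two, scaling="alpha=1, beta=2"),
    _m("Den", "Dennis", "Q", "N", "(a*d-b*c)/sqrt(p*(a+b)*(a+c))", _den,
       "Dennis 1965", False, alpha=_den_alpha, beta=_den_beta,
       scaling="alpha=sqrt(p)/2, beta=(3p-2)/(2*sqrt(p))"),
    _m("dis", "Dispersion", "Q", "N", "(a*d-b*c)/p**2", _dis,
       "Todeschini et al. 2012", False, alpha=_quarter, beta=_half,
       scaling="alpha=1/4, beta=1/2"),
    _m("CT5", "Consonni-Todeschini 5", "Q", "N",
       "(log(1+a*d)-log(1+b*c))/log(1+p**2/4)", _ct5,
       "Consonni & Todeschini 2012", False, alpha=_one, beta=_two,
       scaling="alpha=1, beta=2"),
)

_BY_ID = {m.id: m for m in _CATALOG}


def catalog() -> list[MeasureSpec]:
    """Return the 44 similarity measures in canonical order."""
    return list(_CATALOG)


def get_measure(measure_id: str) -> MeasureSpec:
    """Look up a measure by its short label (e.g. ``"BUB"``)."""
    try:
        return _BY_ID[measure_id]
    except KeyError:
        raise KeyError(
            f"unknown measure id {measure_id!r}; known ids: {', '.join(_BY_ID)}"
        ) from None


def _counts_arrays(counts):
    if isinstance(counts, ContingencyCounts):
        return (
            np.asarray(float(counts.a)),
            np.asarray(float(counts.b)),
            np.asarray(float(counts.c)),
            np.asarray(float(counts.d)),
            True,
        )
    a, b, c, d = (np.asarray(v, dtype=float) for v in counts)
    return a, b, c, d, False


def evaluate_raw(measure: MeasureSpec, counts):
    """Raw (unscaled) value of *measure* on contingency counts.

    *counts* is either a :class:`ContingencyCounts` or a 4-tuple of
    broadcastable arrays ``(a, b, c, d)``.  Degenerate denominators follow
    the catalog convention: if the two fingerprints are identical
    (``b = c = 0``) the coefficient's maximal raw value is returned,
    otherwise the neutral raw value 0.
    """
    a, b, c, d, scalar = _counts_arrays(counts)
    p = a + b + c + d
    guard = _Guard(np.broadcast(a, b, c, d).shape)
    raw = np.asarray(measure._fn(a, b, c, d, p, guard), dtype=float)
    if guard.flag.any():
        identical = (b == 0) & (c == 0)
        max_raw = measure.beta(p) - measure.alpha(p)
        raw = np.where(guard.flag & identical, max_raw, raw)
        raw = np.where(guard.flag & ~identical, 0.0, raw)
    return float(raw) if scalar else raw


_RESCALE_TOL = 1e-9


def rescale(value, measure: MeasureSpec, p):
    """Map a raw coefficient value onto [0, 1] via ``(s + alpha) / beta``.

    Raises :class:`ValueError` when the result leaves [0, 1] by more than a
    numerical tolerance — that signals a formula or scaling bug, not data.
    """
    value = np.asarray(value, dtype=float)
    p = np.asarray(p, dtype=float)
    scaled = (value + measure.alpha(p)) / measure.beta(p)
    if np.any(scaled < -_RESCALE_TOL) or np.any(scaled > 1 + _RESCALE_TOL):
        bad = scaled[(scaled < -_RESCALE_TOL) | (scaled > 1 + _RESCALE_TOL)]
        raise ValueError(
            f"rescaled {measure.id} value outside [0, 1]: {bad.ravel()[:5]!r} "
            f"(raw range/scaling constants are inconsistent)"
        )
    out = np.clip(scaled, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def evaluate(measure: MeasureSpec, counts):
    """Rescaled value of *measure* on contingency counts (in [0, 1])."""
    a, b, c, d, scalar = _counts_arrays(counts)
    raw = evaluate_raw(measure, (a, b, c, d))
    out = rescale(raw, measure, a + b + c + d)
    return float(out) if scalar else out


def catalog_frame():
    """The catalog as a :class:`pandas.DataFrame` (one row per measure)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "id": [m.id for m in _CATALOG],
            "name": [m.full_name for m in _CATALOG],
            "class": [m.class_tag for m in _CATALOG],
            "metricity": [m.metricity_tag for m in _CATALOG],
            "formula": [m.formula for m in _CATALOG],
            "scaling": [m.scaling for m in _CATALOG],
            "self_maximal": [m.self_maximal for m in _CATALOG],
            "order_dependent": [m.order_dependent for m in _CATALOG],
        }
    )
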