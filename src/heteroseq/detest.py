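"""Exact differential-expression test between two sequencing libraries.

The test is the Audic-Claverie posterior-predictive comparison of two raw
counts.  Given ``x`` reads for a gene in a library of ``N1`` total mapped
reads, the predictive probability of observing ``y`` reads in a second library
of ``N2`` reads (library-size ratio ``r = N2/N1``) is

    p(y | x) = r**y * (x + y)! / (x! * y! * (1 + r)**(x + y + 1))

which is the negative-binomial pmf with ``x + 1`` successes and success
probability ``1/(1+r)`` -- the form used here so that pmf/cdf/sf come from
``scipy.stats.nbinom`` while the log-space formula above is kept as an
independent expression for cross-checking.  The two-sided p-value uses
minimum-likelihood ordering: the total predictive mass of all outcomes ``y'``
no more probable than the observed ``y``.

Because the study sequenced one pooled library per line, the test models
technical (Poisson) sampling only; there is no replicate-level dispersion.

Four contrasts are run per gene: P1 vs F1, P2 vs F1, F1 against its expected
midparent count (the additivity test feeding the dominance classifier), and
P1 vs P2 (which fixes the parents' relative order).  Benjamini-Hochberg
correction is applied within each contrast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import nbinom
from statsmodels.stats.multitest import multipletests

from .io_tables import CountTable
from .quantify import rpkm

#: Contrast labels; the first member is the reference ("x") library.
CONTRASTS = ("P1_vs_F1", "P2_vs_F1", "MP_vs_F1", "P1_vs_P2")

_LOG_TIE_TOL = 1e-9  # outcomes within this log-pmf slack of the observed one count as ties


def _check_libs(n1, n2) -> None:
    if n1 < 1 or n2 < 1:
        raise ValueError("library sizes must be >= 1")


def _log_pmf(y, x, r):
    """log p(y|x) via log-gamma; overflow-safe for any counts."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    return (
        y * np.log(r)
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * np.log1p(r)
    )


def ac_probability(x, y, n1, n2):
    """Predictive probability p(y|x) of count ``y`` given ``x`` and ``r=N2/N1``.

    Sums to 1 over ``y`` for fixed ``x``.  Vectorized over ``x`` and ``y``.
    """
    _check_libs(n1, n2)
    x = np.asarray(x)
    y = np.asarray(y)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative")
    out = np.exp(_log_pmf(y, x, n2 / n1))
    return out.item() if out.ndim == 0 else out


def _bisect_left_side(x, mode, logt, r):
    """Largest j in [0, mode] with log-pmf(j) <= logt (pmf rises to the mode).

    Returns j and a found-mask; vectorized binary search.
    """
    found = _log_pmf(np.zeros_like(mode), x, r) <= logt
    lo = np.zeros_like(mode)
    hi = np.where(found, mode, np.zeros_like(mode))
    while True:
        active = found & (lo < hi)
        if not active.any():
            break
        mid = (lo + hi + 1) // 2
        ok = _log_pmf(mid, x, r) <= logt
        lo = np.where(active & ok, mid, lo)
        hi = np.where(active & ~ok, mid - 1, hi)
    return lo, found


def _bisect_right_side(x, mode, logt, r):
    """Smallest j >= mode with log-pmf(j) <= logt (pmf falls after the mode)."""
    # bracket: double outward until the pmf has dropped below the target
    hi = mode + 4 * np.sqrt((x + 1.0) * r * (1 + r)) + 16
    hi = hi.astype(np.int64)
    while True:
        over = _log_pmf(hi, x, r) > logt
        if not over.any():
            break
        hi = np.where(over, 2 * hi + 16, hi)
    lo = mode.copy()
    while True:
        active = lo < hi
        if not active.any():
            break
        mid = (lo + hi) // 2
        ok = _log_pmf(mid, x, r) <= logt
        hi = np.where(active & ok, mid, hi)
        lo = np.where(active & ~ok, mid + 1, lo)
    return lo


def ac_test(x, y, n1, n2, sided: str = "two-sided"):
    """Exact p-value for a count difference between two libraries.

    ``sided='two-sided'`` (default) uses minimum-likelihood ordering:
    ``p = sum over y' of p(y'|x) for all y' with p(y'|x) <= p(y|x)``, capped
    at 1.  ``'greater'``/``'less'`` give upper/lower predictive tails of y.
    Vectorized over paired ``x``/``y`` arrays.
    """
    _check_libs(n1, n2)
    scalar = np.isscalar(x) and np.isscalar(y)
    x = np.atleast_1d(np.asarray(x, dtype=np.int64))
    y = np.atleast_1d(np.asarray(y, dtype=np.int64))
    if x.shape != y.shape:
        x, y = np.broadcast_arrays(x, y)
        x, y = x.copy(), y.copy()
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative")
    r = n2 / n1
    q = 1.0 / (1.0 + r)  # nbinom success probability, n = x + 1
    if sided == "greater":
        p = nbinom.sf(y - 1, x + 1, q)
    elif sided == "less":
        p = nbinom.cdf(y, x + 1, q)
    elif sided == "two-sided":
        mode = np.floor(x * r).astype(np.int64)
        logt = _log_pmf(y, x, r) + _LOG_TIE_TOL
        p = np.ones(x.shape, dtype=float)
        modal = _log_pmf(mode, x, r) <= logt  # observed outcome is (tied with) the mode
        right = ~modal & (y > mode)
        if right.any():
            xr, yr, mr = x[right], y[right], mode[right]
            tr = logt[right]
            p_tail = nbinom.sf(yr - 1, xr + 1, q)
            j, found = _bisect_left_side(xr, mr, tr, r)
            p_left = np.where(found, nbinom.cdf(j, xr + 1, q), 0.0)
            p[right] = p_tail + p_left
        left = ~modal & (y < mode)
        if left.any():
            xl, yl, ml = x[left], y[left], mode[left]
            tl = logt[left]
            p_low = nbinom.cdf(yl, xl + 1, q)
            j = _bisect_right_side(xl, ml, tl, r)
            p_high = nbinom.sf(j - 1, xl + 1, q)
            p[left] = p_low + p_high
        p = np.clip(p, 0.0, 1.0)
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    return float(p[0]) if scalar else p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone in rank order, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def midparent_counts(table: CountTable, rounding: str = "round") -> np.ndarray:
    """Expected midparent count per gene, placed on the F1 library's scale.

    ``round(((x_P1/N_P1 + x_P2/N_P2) / 2) * N_F1)`` -- the additivity
    reference the F1 count is tested against with N1 = N2 = N_F1.
    """
    rate = (
        table.counts("P1") / table.lib_sizes["P1"]
        + table.counts("P2") / table.lib_sizes["P2"]
    ) / 2.0
    raw = rate * table.lib_sizes["F1"]
    if rounding == "round":
        return np.rint(raw).astype(np.int64)
    if rounding == "floor":
        return np.floor(raw).astype(np.int64)
    if rounding == "ceil":
        return np.ceil(raw).astype(np.int64)
    raise ValueError(f"unknown rounding {rounding!r}")


def run_contrasts(
    table: CountTable,
    alpha: float = 0.05,
    min_log2fc: float = 0.0,
    pseudocount: float = 1.0,
    sided: str = "two-sided",
    midparent_rounding: str = "round",
) -> pd.DataFrame:
    """Run the four per-gene exact-test contrasts with BH correction.

    Returns a long frame with one row per (gene, contrast):
    ``gene_id, contrast, x, y, p_value, fdr, log2_ratio, sign, direction``.
    ``sign`` is +1/0/-1 for the second library (F1, or P2 in the parent
    contrast) significantly higher / not significant / lower; ``direction``
    spells it out (``up_in_F1`` etc.).  A gene is a DEG when significant in at
    least one of the two parental contrasts.  ``min_log2fc`` additionally
    requires ``|log2_ratio|`` (RPKM scale, with pseudocount) to clear a floor
    before a contrast counts as significant; it is 0 (off) by default.
    """
    lengths = table.genes["length_bp"].to_numpy()
    n_p1, n_p2, n_f1 = (table.lib_sizes[k] for k in ("P1", "P2", "F1"))
    mp = midparent_counts(table, midparent_rounding)
    specs = {
        "P1_vs_F1": (table.counts("P1"), table.counts("F1"), n_p1, n_f1),
        "P2_vs_F1": (table.counts("P2"), table.counts("F1"), n_p2, n_f1),
        "MP_vs_F1": (mp, table.counts("F1"), n_f1, n_f1),
        "P1_vs_P2": (table.counts("P1"), table.counts("P2"), n_p1, n_p2),
    }
    frames = []
    for contrast, (x, y, n1, n2) in specs.items():
        p = ac_test(x, y, n1, n2, sided=sided)
        p = np.atleast_1d(p)
        fdr = bh_fdr(p)
        rpkm_x = rpkm(x, lengths, n1)
        rpkm_y = rpkm(y, lengths, n2)
        log2_ratio = np.log2((rpkm_y + pseudocount) / (rpkm_x + pseudocount))
        raw_sign = np.sign(y / n2 - x / n1).astype(int)
        significant = (fdr < alpha) & (np.abs(log2_ratio) >= min_log2fc)
        sign = np.where(significant, raw_sign, 0)
        second = "F1" if contrast.endswith("F1") else "P2"
        direction = np.select(
            [sign > 0, sign < 0], [f"up_in_{second}", f"down_in_{second}"], "none"
        )
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": table.gene_ids,
                    "contrast": contrast,
                    "x": x,
                    "y": y,
                    "p_value": p,
                    "fdr": fdr,
                    "log2_ratio": log2_ratio,
                    "sign": sign,
                    "direction": direction,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def deg_gene_ids(de: pd.DataFrame) -> frozenset[str]:
    """Genes significant in at least one parental contrast (the DEG set)."""
    parental = de[de["contrast"].isin(["P1_vs_F1", "P2_vs_F1"]) & (de["sign"] != 0)]
    return frozenset(parental["gene_id"])
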