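"""Gene-action (dominance-mode) classification and midparent heterosis.

Every differentially expressed gene is assigned exactly one of eight modes by
a fixed decision tree over three signed exact-test outcomes (F1 vs P1, F1 vs
P2, F1 vs midparent; each +1 / 0 / -1) and the parents' significance-backed
order:

1. F1 indistinguishable from the midparent            -> ADD (additivity)
2. F1 significantly above both parents                -> ODO (overdominance)
3. F1 significantly below both parents                -> UDO (underdominance)
4. F1 = the significantly higher parent, above the lower -> HPD
5. F1 = the significantly lower parent, below the higher -> LPD
6. F1 strictly between significantly different parents and off the
   midparent: above it -> PPD, below it -> NPD (partial dominance)
7. anything else                                      -> OTHER

"=" is operationalized as non-significance of the corresponding contrast at
the configured FDR; when the parents do not differ significantly, HPD/LPD/
PPD/NPD are unreachable by construction.

Midparent heterosis is reported on the percent scale where the midparent maps
to 100::

    MPH = (h - (P1 + P2)/2) / ((P1 + P2)/2) * 100 + 100
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MODES = ("ADD", "HPD", "LPD", "ODO", "UDO", "PPD", "NPD", "OTHER")
NONADDITIVE_MODES = ("HPD", "LPD", "ODO", "UDO", "PPD", "NPD")


def mph(h, p1, p2):
    """Midparent heterosis percent; midparent performance maps to 100."""
    h = np.asarray(h, dtype=float)
    midparent = (np.asarray(p1, dtype=float) + np.asarray(p2, dtype=float)) / 2.0
    if np.any(midparent == 0):
        raise ZeroDivisionError("midparent value is zero; MPH undefined")
    out = (h - midparent) / midparent * 100.0 + 100.0
    return out.item() if out.ndim == 0 else out


def classify(sig_vs_p1: int, sig_vs_p2: int, sig_vs_mp: int, parent_sign: int) -> str:
    """Assign a dominance mode from three signed outcomes and the parent order.

    ``sig_vs_p1``/``sig_vs_p2``/``sig_vs_mp`` are +1 (F1 significantly
    higher), 0 (not significant) or -1; ``parent_sign`` is +1 when P1 is
    significantly higher than P2, -1 when lower, 0 when the parents do not
    differ.
    """
    for v in (sig_vs_p1, sig_vs_p2, sig_vs_mp, parent_sign):
        if v not in (-1, 0, 1):
            raise ValueError(f"signed outcome must be -1/0/+1, got {v!r}")
    if sig_vs_mp == 0:
        return "ADD"
    if sig_vs_p1 == 1 and sig_vs_p2 == 1:
        return "ODO"
    if sig_vs_p1 == -1 and sig_vs_p2 == -1:
        return "UDO"
    if parent_sign != 0:
        sig_hi = sig_vs_p1 if parent_sign > 0 else sig_vs_p2
        sig_lo = sig_vs_p2 if parent_sign > 0 else sig_vs_p1
        if sig_hi == 0 and sig_lo == 1:
            return "HPD"
        if sig_lo == 0 and sig_hi == -1:
            return "LPD"
        if sig_hi == -1 and sig_lo == 1:
            return "PPD" if sig_vs_mp == 1 else "NPD"
    return "OTHER"


def _classify_vec(s1, s2, smp, ps):
    sig_hi = np.where(ps > 0, s1, s2)
    sig_lo = np.where(ps > 0, s2, s1)
    ordered = ps != 0
    conditions = [
        smp == 0,
        (s1 == 1) & (s2 == 1),
        (s1 == -1) & (s2 == -1),
        ordered & (sig_hi == 0) & (sig_lo == 1),
        ordered & (sig_lo == 0) & (sig_hi == -1),
        ordered & (sig_hi == -1) & (sig_lo == 1) & (smp == 1),
        ordered & (sig_hi == -1) & (sig_lo == 1) & (smp == -1),
    ]
    choices = ["ADD", "ODO", "UDO", "HPD", "LPD", "PPD", "NPD"]
    return np.select(conditions, choices, "OTHER")


def classify_calls(de: pd.DataFrame, expr: pd.DataFrame) -> pd.DataFrame:
    """Classify every DEG and attach its midparent heterosis value.

    ``de`` is the long contrast frame from :func:`heteroseq.detest.run_contrasts`
    (all four contrasts required for every gene); ``expr`` the expression frame
    from :func:`heteroseq.quantify.call_expressed` supplying RPKM values for
    MPH.  Returns one row per DEG: ``gene_id, mode, mph, sig_vs_P1, sig_vs_P2,
    sig_vs_MP, parent_sign``.  MPH is NaN for the rare DEG whose parents are
    both at zero RPKM (activated in the hybrid; midparent undefined).
    """
    wide = de.pivot(index="gene_id", columns="contrast", values="sign")
    missing_cols = [c for c in ("P1_vs_F1", "P2_vs_F1", "MP_vs_F1", "P1_vs_P2")
                    if c not in wide.columns]
    if missing_cols:
        raise ValueError(f"missing contrast(s) {missing_cols} in DE results")
    incomplete = wide.isna().any(axis=1)
    if incomplete.any():
        raise ValueError(
            f"gene {wide.index[incomplete][0]!r} is missing a contrast outcome"
        )
    wide = wide.astype(int)
    deg = wide[(wide["P1_vs_F1"] != 0) | (wide["P2_vs_F1"] != 0)]

    s1 = deg["P1_vs_F1"].to_numpy()
    s2 = deg["P2_vs_F1"].to_numpy()
    smp = deg["MP_vs_F1"].to_numpy()
    ps = -deg["P1_vs_P2"].to_numpy()  # +1 when P1 significantly above P2
    modes = _classify_vec(s1, s2, smp, ps)

    rp = expr.set_index("gene_id").reindex(deg.index)
    midparent = (rp["rpkm_P1"].to_numpy() + rp["rpkm_P2"].to_numpy()) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        mph_vals = np.where(
            midparent > 0,
            rp["rpkm_F1"].to_numpy() / midparent * 100.0,
            np.nan,
        )
    out = pd.DataFrame(
        {
            "gene_id": deg.index,
            "mode": modes,
            "mph": mph_vals,
            "sig_vs_P1": s1,
            "sig_vs_P2": s2,
            "sig_vs_MP": smp,
            "parent_sign": ps,
        }
    )
    return out.reset_index(drop=True)


def summarize_modes(calls: pd.DataFrame) -> pd.DataFrame:
    """Mode-count summary in the style of a dominance-pattern table.

    Rows: Additivity, Nonadditivity, Others, the six nonadditive modes, and
    Total.  Percentages (two decimals) are of the grand total for the three
    top-level rows and of the nonadditive total for the individual modes,
    matching the arithmetic convention of published dominance tables.
    """
    n = len(calls)
    by_mode = calls["mode"].value_counts() if n else pd.Series(dtype=int)
    count = {m: int(by_mode.get(m, 0)) for m in MODES}
    nonadd = sum(count[m] for m in NONADDITIVE_MODES)

    def pct(k: int, denom: int) -> float:
        return round(100.0 * k / denom, 2) if denom else 0.0

    rows = [
        ("Additivity", count["ADD"], pct(count["ADD"], n)),
        ("Nonadditivity", nonadd, pct(nonadd, n)),
        ("Others", count["OTHER"], pct(count["OTHER"], n)),
    ]
    rows += [
        (f"{m}", count[m], pct(count[m], nonadd)) for m in NONADDITIVE_MODES
    ]
    rows.append(("Total", n, 100.0 if n else 0.0))
    return pd.DataFrame(rows, columns=["category", "number", "percentage"])
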