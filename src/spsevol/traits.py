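"""Selenium-utilization trait profiling from genome x marker matrices.

Two traits are inferred from gene markers. The Sec trait (selenocysteine
usage) requires selenophosphate synthetase (SelD) together with at least one
of bacterial Sec synthase (SelA), tRNAsec, or a nonempty selenoproteome.
The SeU trait (2-selenouridine in tRNA) requires SelD plus selenouridine
synthase (ybbB). Genomes carrying SelD but neither trait are "orphan SelD"
(the Enterococcus-like configuration, hinting at a third selenium use).

Trait co-occurrence is tested with a one-tailed Fisher exact test
(hypergeometric upper tail, enrichment direction), computed in log space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

MARKER_COLUMNS = [
    "SelD_present",
    "SelD_residue",
    "SelA",
    "ybbB",
    "tRNAsec",
    "selenoproteome_size",
]


@dataclass(frozen=True)
class TraitCall:
    genome_id: str
    sec: bool
    seu: bool
    orphan_selD: bool


def validate_marker_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """Check the marker-matrix contract; returns the frame unchanged."""
    missing = [c for c in MARKER_COLUMNS if c not in m.columns]
    if missing:
        raise ValueError(f"marker matrix missing columns {missing}")
    if (m["selenoproteome_size"] < 0).any():
        raise ValueError("negative selenoproteome_size")
    bad = (m["SelD_residue"] != "none") & ~m["SelD_present"].astype(bool)
    if bad.any():
        raise ValueError("SelD_residue set without SelD_present")
    return m


def call_traits(m: pd.DataFrame) -> list[TraitCall]:
    """Per-genome trait calls from the marker matrix (row-independent)."""
    validate_marker_matrix(m)
    calls = []
    for gid, row in m.iterrows():
        seld = bool(row["SelD_present"])
        sec = seld and (
            bool(row["SelA"])
            or bool(row["tRNAsec"])
            or int(row["selenoproteome_size"]) > 0
        )
        seu = seld and bool(row["ybbB"])
        calls.append(TraitCall(str(gid), sec, seu, seld and not sec and not seu))
    return calls


def fisher_overlap_test(calls: list[TraitCall]) -> float:
    """One-tailed Fisher exact p for Sec/SeU over-co-occurrence.

    With margins fixed to the two trait counts, p = P(X >= observed both
    count) under the hypergeometric null; the sum is carried out in log
    space via log-gamma.
    """
    if not calls:
        raise ValueError("empty trait-call list")
    n = len(calls)
    n_sec = sum(c.sec for c in calls)
    n_seu = sum(c.seu for c in calls)
    n_both = sum(c.sec and c.seu for c in calls)
    return hypergeom_upper_tail(n, n_sec, n_seu, n_both)


def _log_comb(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper_tail(n: int, k1: int, k2: int, observed: int) -> float:
    """P(X >= observed) for X ~ Hypergeom(n, k1, k2), via log-gamma."""
    lo = max(0, k1 + k2 - n)
    hi = min(k1, k2)
    if observed <= lo:
        return 1.0
    denom = _log_comb(n, k2)
    logs = [
        _log_comb(k1, k) + _log_comb(n - k1, k2 - k) - denom
        for k in range(observed, hi + 1)
    ]
    if not logs:
        return 0.0
    mx = max(logs)
    return float(np.exp(mx) * np.sum(np.exp(np.array(logs) - mx)))


def summarize_panel(calls: list[TraitCall], m: pd.DataFrame | None = None) -> dict:
    """Panel-level frequency table.

    Fractions of genomes carrying SelD, the Sec trait, the SeU trait and
    both; when the marker matrix is supplied, also the fraction of
    SelD-bearing genomes whose SelD carries a Sec (U) residue and the
    fraction with SelA and/or ybbB.
    """
    n = len(calls)
    if n == 0:
        return {k: 0.0 for k in ("n", "frac_selD", "frac_sec", "frac_seu", "frac_both")}
    seld = sum(c.sec or c.seu or c.orphan_selD for c in calls)
    out = {
        "n": n,
        "frac_selD": seld / n,
        "frac_sec": sum(c.sec for c in calls) / n,
        "frac_seu": sum(c.seu for c in calls) / n,
        "frac_both": sum(c.sec and c.seu for c in calls) / n,
        "frac_orphan_selD": sum(c.orphan_selD for c in calls) / n,
    }
    if m is not None and seld > 0:
        validate_marker_matrix(m)
        carriers = m[m["SelD_present"].astype(bool)]
        out["frac_selD_sec_residue"] = float((carriers["SelD_residue"] == "U").mean())
        out["frac_selD_with_selA_or_ybbB"] = float(
            (carriers["SelA"].astype(bool) | carriers["ybbB"].astype(bool)).mean()
        )
    return out


def table_from_percentages(
    n: int, pct_sec: float, pct_seu: float, pct_both: float
) -> tuple[int, int, int, int]:
    """Round printed trait percentages to a 2x2 table (both, sec-only,
    seu-only, neither); the rounding residual lands in "neither"."""
    n_sec = round(n * pct_sec)
    n_seu = round(n * pct_seu)
    n_both = round(n * pct_both)
    sec_only = n_sec - n_both
    seu_only = n_seu - n_both
    neither = n - n_both - sec_only - seu_only
    return n_both, sec_only, seu_only, neither
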