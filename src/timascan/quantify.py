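"""Per-sample monocyte metrics: the substrate of all downstream statistics.

The assay's headline quantity is the percentage of GFAP+ events among CD16+
monocytes, where "CD16+ monocytes" means the union of the intermediate
(CD14+CD16+) and non-classical (CD14-CD16+) subsets. Because positivity is
called against the lymphocyte background at quantile q, a raw positive
fraction carries an expected false-positive floor of (1-q); the optional
background-corrected estimator inverts m = f + (1-f)(1-q). Raw fractions are
the default output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gating import GatingResult, PositivityCall

__all__ = ["MonocyteProfile", "monocyte_profile", "background_corrected_pct"]

CD16_POPULATIONS = ("intermediate_mono", "nonclassical_mono")


@dataclass
class MonocyteProfile:
    """Derived per-sample metrics; percentages in [0, 100], counts in cells/ul."""

    sample_id: str
    n_leukocyte_events: int
    n_cd16_events: int
    n_nonclassical_events: int
    pct_monocytes_of_leukocytes: float
    pct_classical: float
    pct_intermediate: float
    pct_nonclassical: float
    pct_gfap_cd16: float | None
    pct_gfap_nonclassical: float | None
    pct_gfap_intermediate: float | None
    pct_plp1_cd16: float | None
    pct_dual_cd16: float | None
    abs_gfap_cd16: float | None
    abs_counts: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def as_row(self) -> dict:
        row = {k: v for k, v in self.__dict__.items()
               if k not in ("abs_counts", "flags")}
        row.update({f"abs_{k}": v for k, v in self.abs_counts.items()})
        row["flags"] = ";".join(self.flags)
        return row


def background_corrected_pct(pct_raw: float, quantile: float) -> float:
    """Invert the additive lymphocyte-background false-positive rate.

    Solves m = f + (1 - f) * (1 - q) for f, clipped at 0.
    """
    eps = 1.0 - quantile
    return max((pct_raw / 100.0 - eps) / (1.0 - eps), 0.0) * 100.0


def _pct(numer: int, denom: int) -> float | None:
    return 100.0 * numer / denom if denom > 0 else None


def monocyte_profile(
    gating: GatingResult,
    gfap: PositivityCall | None = None,
    plp1: PositivityCall | None = None,
    wbc_count: float | None = None,
    min_cd16_events: int = 100,
    background_correct: bool = False,
) -> MonocyteProfile:
    """Reduce a gated, positivity-labelled sample to its monocyte metrics.

    Absolute counts are (population events / leukocyte events) x wbc_count and
    are omitted (not zero) when the white-cell count is absent. Small CD16+
    denominators yield a low-confidence flag; a zero denominator yields
    missing percentages plus a flag.
    """
    counts = gating.population_counts
    n_leuk = gating.stage_counts["leukocytes"]
    n_mono = counts["monocyte"]
    n_cd16 = counts["intermediate_mono"] + counts["nonclassical_mono"]
    n_nc = counts["nonclassical_mono"]
    flags: list[str] = []

    if n_cd16 == 0:
        flags.append("zero CD16+ denominator")
    elif n_cd16 < min_cd16_events:
        flags.append("low-confidence: CD16+ denominator below minimum")
    if n_nc == 0:
        flags.append("zero non-classical denominator")

    cd16_mask = gating.mask(*CD16_POPULATIONS)
    nc_mask = gating.mask("nonclassical_mono")
    int_mask = gating.mask("intermediate_mono")

    def marker_pct(call: PositivityCall | None, mask, denom) -> float | None:
        if call is None or denom == 0:
            return None
        pct = _pct(int(np.sum(call.flags & mask)), denom)
        if background_correct and pct is not None:
            pct = background_corrected_pct(pct, call.quantile)
        return pct

    pct_gfap_cd16 = marker_pct(gfap, cd16_mask, n_cd16)
    pct_gfap_nc = marker_pct(gfap, nc_mask, n_nc)
    pct_gfap_int = marker_pct(gfap, int_mask, counts["intermediate_mono"])
    pct_plp1_cd16 = marker_pct(plp1, cd16_mask, n_cd16)

    pct_dual = None
    if gfap is not None and plp1 is not None and n_cd16 > 0:
        dual = int(np.sum(gfap.flags & plp1.flags & cd16_mask))
        pct_dual = _pct(dual, n_cd16)

    abs_counts: dict[str, float] = {}
    abs_gfap_cd16 = None
    if wbc_count is not None and np.isfinite(wbc_count) and n_leuk > 0:
        for pop in ("monocyte", "classical_mono", "intermediate_mono",
                    "nonclassical_mono", "lymphocyte", "dendritic"):
            abs_counts[pop] = counts[pop] / n_leuk * wbc_count
        if gfap is not None:
            n_pos = int(np.sum(gfap.flags & cd16_mask))
            abs_gfap_cd16 = n_pos / n_leuk * wbc_count

    return MonocyteProfile(
        sample_id=gating.sample_id,
        n_leukocyte_events=n_leuk,
        n_cd16_events=n_cd16,
        n_nonclassical_events=n_nc,
        pct_monocytes_of_leukocytes=_pct(n_mono, n_leuk) or 0.0,
        pct_classical=_pct(counts["classical_mono"], n_mono) or 0.0,
        pct_intermediate=_pct(counts["intermediate_mono"], n_mono) or 0.0,
        pct_nonclassical=_pct(counts["nonclassical_mono"], n_mono) or 0.0,
        pct_gfap_cd16=pct_gfap_cd16,
        pct_gfap_nonclassical=pct_gfap_nc,
        pct_gfap_intermediate=pct_gfap_int,
        pct_plp1_cd16=pct_plp1_cd16,
        pct_dual_cd16=pct_dual,
        abs_gfap_cd16=abs_gfap_cd16,
        abs_counts=abs_counts,
        flags=flags,
    )
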