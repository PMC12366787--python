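"""Taxon-level community composition and bacterivory-share accounting.

Given a taxon table (name, class, feeding mode, mean cell-specific uptake
where measurable, and proportion of the total ciliate community), the share
of total ciliate bacterivory attributable to taxon i is

    share_i = 100 · U_i·p_i / Σ_j U_j·p_j

over the taxa with measured uptake — i.e. uptake weighted by relative
abundance. Taxa without uptake (predators, algivores, detritivores)
contribute zero bacterivory but are carried in composition summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["TaxonRecord", "FEEDING_MODES", "bacterivory_shares",
           "composition_summary"]

FEEDING_MODES = ("bacterivorous", "omnivorous", "predatory", "algivorous",
                 "detritivorous", "unknown")


@dataclass
class TaxonRecord:
    """One ciliate taxon's feeding data and community proportion."""

    name: str
    class_name: str
    feeding_mode: str
    proportion_pct: float
    uptake_mean: float | None = None  # prey cell-1 h-1; None if no uptake
    uptake_sd: float | None = None

    def __post_init__(self) -> None:
        if self.feeding_mode not in FEEDING_MODES:
            raise ValueError(
                f"feeding_mode must be one of {FEEDING_MODES}, "
                f"got {self.feeding_mode!r}"
            )
        if self.proportion_pct < 0:
            raise ValueError("proportion_pct must be non-negative")
        if self.uptake_mean is not None and self.uptake_mean < 0:
            raise ValueError("uptake_mean must be non-negative when present")


def bacterivory_shares(taxa: list[TaxonRecord]) -> pd.DataFrame:
    """Share of total community bacterivory per taxon (%).

    Shares are computed from mean uptake × community proportion; taxa
    without measured uptake contribute 0. Shares over the grazing taxa sum
    to 100 and are invariant under rescaling all uptakes by a common factor.
    """
    grazers = [t for t in taxa if t.uptake_mean is not None]
    if not grazers:
        raise ValueError("no taxon with measured uptake; shares undefined")
    products = {t.name: t.uptake_mean * t.proportion_pct for t in grazers}
    total = sum(products.values())
    if total <= 0:
        raise ValueError("total uptake-weighted proportion is zero")
    rows = [
        {"name": t.name,
         "share_pct": 100.0 * products[t.name] / total if t.uptake_mean is not None else 0.0}
        for t in taxa
    ]
    return pd.DataFrame(rows)


def composition_summary(taxa: list[TaxonRecord]) -> pd.DataFrame:
    """Community proportion summed by feeding mode, with the residual to
    100% reported as unidentified."""
    totals = dict.fromkeys(FEEDING_MODES, 0.0)
    for t in taxa:
        totals[t.feeding_mode] += t.proportion_pct
    grand = sum(totals.values())
    if grand > 100.0 + 1e-9:
        raise ValueError(f"proportions sum to {grand:.4f}% > 100%")
    rows = [{"feeding_mode": m, "total_pct": totals[m]} for m in FEEDING_MODES]
    rows.append({"feeding_mode": "unidentified", "total_pct": 100.0 - grand})
    return pd.DataFrame(rows)
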