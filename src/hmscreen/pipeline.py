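"""Convenience drivers composing the pipeline stages.

``build_region_specs`` bridges TSS-relative substitution positions into the
index-based regions the clustering test consumes; ``reconstruct_screen``
re-runs the whole published screen from the embedded reference tables:
candidate filtering from the misregulation flags, tissue prioritization,
substitution proportions, and the clustering test on the GA22690 fragment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from . import datasets
from .hotspot import HotspotResult, RegionSpec, hotspot_pvalue
from .substitutions import tss_to_index

__all__ = ["build_region_specs", "reconstruct_screen", "ScreenResult"]

_DOMAIN_WINDOWS = {
    "P": (-200, 200),
    "PP": (-500, -201),
}


def build_region_specs(
    gene: str,
    tss_positions: Sequence[int],
    tss_start: int,
    tss_end: int,
    labels: Sequence[str] = ("whole", "PD", "PP", "P"),
) -> list[RegionSpec]:
    """RegionSpecs for the whole fragment and/or the upstream domain windows.

    Regions with fewer than one event are skipped (no test is defined).
    Domain windows are clipped to the fragment; ``PD`` runs from the
    fragment start to -501.
    """
    positions = sorted(int(p) for p in tss_positions)
    specs: list[RegionSpec] = []
    for label in labels:
        if label in ("whole", "whole_fragment"):
            lo, hi = tss_start, tss_end
        elif label == "PD":
            lo, hi = tss_start, -501
        elif label in _DOMAIN_WINDOWS:
            lo, hi = _DOMAIN_WINDOWS[label]
            lo, hi = max(lo, tss_start), min(hi, tss_end)
        else:
            raise ValueError(f"unknown region label {label!r}")
        if lo >= hi:
            continue
        inside = [p for p in positions if lo <= p <= hi]
        if not inside:
            continue
        indices = tuple(tss_to_index(p, lo, hi) for p in inside)
        specs.append(
            RegionSpec(
                gene=gene,
                region_label="whole_fragment" if label.startswith("whole") else label,
                length=_region_length(lo, hi),
                event_indices=indices,
                tss_interval=(lo, hi),
            )
        )
    return specs


def _region_length(lo: int, hi: int) -> int:
    n = hi - lo + 1
    if lo < 0 < hi:
        n -= 1
    return n


@dataclass
class ScreenResult:
    """Everything the reconstruction computes, in one bundle."""

    misregulated_bc: list[str]
    misregulated_bc4: list[str]
    retained_candidates: list[str]
    ovd_targets: set[str]
    enrichment: dict[str, object]
    prioritized: list[str]
    drop_reasons: dict[str, str]
    proportions: dict[str, float]
    hotspots: dict[str, HotspotResult] = field(default_factory=dict)


def reconstruct_screen(n_sim: int = 100_000, seed: int = 0) -> ScreenResult:
    """Re-run the published screen from the embedded reference tables."""
    from .candidates import (
        annotate_ovd,
        apply_exclusion_rule,
        flag_fertile_misregulation,
        identify_ovd_targets,
    )
    from .substitutions import substitution_proportion
    from .tissue import TissueProfile, enrichment_call, prioritize

    flags = datasets.load_flags()
    misreg = flag_fertile_misregulation(flags)
    bc = sorted(g for g, v in misreg.items() if v["bc"])
    bc4 = sorted(g for g, v in misreg.items() if "BC4" in v["bc"])
    statuses = apply_exclusion_rule(flags)
    ovd = identify_ovd_targets(datasets.OVD_SE_SIGNIFICANT)
    statuses = annotate_ovd(statuses, ovd)
    retained = [s.gene for s in statuses if s.retained_candidate]

    calls = [
        enrichment_call(TissueProfile(gene=g, dcq_by_tissue=prof))
        for g, prof in datasets.TISSUE_PROFILES.items()
    ]
    prioritized, reasons = prioritize([g for g in retained if g in datasets.TISSUE_PROFILES], calls)

    proportions = {}
    for gene, (lo, hi, reported_n) in datasets.FRAGMENTS.items():
        n_events = len(datasets.FIXED_SUBSTITUTIONS[gene])
        _, rounded = substitution_proportion(n_events, reported_n)
        proportions[gene] = rounded

    hotspots: dict[str, HotspotResult] = {}
    lo, hi, _ = datasets.FRAGMENTS["GA22690"]
    positions = [p for p, *_ in datasets.FIXED_SUBSTITUTIONS["GA22690"]]
    for spec in build_region_specs("GA22690", positions, lo, hi, labels=("whole", "PD")):
        hotspots[spec.region_label] = hotspot_pvalue(spec, n_sim=n_sim, seed=seed)

    return ScreenResult(
        misregulated_bc=bc,
        misregulated_bc4=bc4,
        retained_candidates=retained,
        ovd_targets=ovd,
        enrichment={c.gene: c for c in calls},
        prioritized=prioritized,
        drop_reasons=reasons,
        proportions=proportions,
        hotspots=hotspots,
    )
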