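"""Tissue-enrichment calls and expression-extremes prioritization.

Candidate hybrid-male-sterility genes act on sperm, so candidates are
prioritized toward genes expressed in the testes (T, where spermatogenesis
happens) over the accessory glands (AG, seminal fluid).  Mean ΔCq per
tissue summarises expression level on a log2 scale (higher = more
expressed).

The enrichment call follows the magnitude-ratio convention of the source
dataset: ratio = |ΔCq(T)| / |ΔCq(AG)| rounded to two decimals, with the
fold change taken as the reciprocal of the *rounded* ratio for
testes-enriched genes and the ratio itself for AG-enriched ones (so fold
change >= 1 always).  This is a log-scale artifact, not a linear expression
ratio; a supplementary 2^(ΔCq(T) − ΔCq(AG)) linear fold is emitted for
interpretability.  Genes very lowly expressed everywhere (all tissue
ΔCq < −10) or very highly expressed everywhere (all tissue ΔCq > −5) are
filtered out, as are AG-enriched genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = ["TissueProfile", "EnrichmentCall", "enrichment_call", "prioritize"]

TISSUES = ("T", "SV", "AG", "EB")
LOW_EXPRESSION_DCQ = -10.0
HIGH_EXPRESSION_DCQ = -5.0


@dataclass(frozen=True)
class TissueProfile:
    gene: str
    dcq_by_tissue: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = {"T", "AG"} - set(self.dcq_by_tissue)
        if missing:
            raise ValueError(f"{self.gene}: tissue profile lacks {sorted(missing)}")


@dataclass(frozen=True)
class EnrichmentCall:
    gene: str
    ratio: float  # |T|/|AG| rounded to 2 decimals
    ratio_unrounded: float
    fold_change: float  # >= 1; reciprocal of rounded ratio when testes-enriched
    fold_change_unrounded: float
    enriched_tissue: str | None  # "T", "AG", or None when tied
    low_expressed: bool
    high_expressed: bool
    linear_fold_t_over_ag: float  # supplementary 2^(dcq_T - dcq_AG)


def enrichment_call(
    profile: TissueProfile,
    low_threshold: float = LOW_EXPRESSION_DCQ,
    high_threshold: float = HIGH_EXPRESSION_DCQ,
) -> EnrichmentCall:
    """Tissue-enrichment call for one gene from its mean ΔCq per tissue."""
    dcq = dict(profile.dcq_by_tissue)
    t, ag = float(dcq["T"]), float(dcq["AG"])
    if ag == 0:
        raise ValueError(f"{profile.gene}: ΔCq(AG) = 0, magnitude ratio undefined")
    ratio_raw = abs(t) / abs(ag)
    ratio = round(ratio_raw, 2)
    if t > ag:
        enriched = "T"
    elif t < ag:
        enriched = "AG"
    else:
        enriched = None  # tie: unclassified
    # fold change expresses the magnitude imbalance symmetrically (>= 1):
    # the reciprocal of the ROUNDED ratio below 1, the ratio itself above
    if ratio < 1:
        fold = round(1.0 / ratio, 2) if ratio > 0 else float("inf")
    else:
        fold = ratio
    fold_raw = max(ratio_raw, 1.0 / ratio_raw) if ratio_raw > 0 else float("inf")
    values = [float(v) for v in dcq.values()]
    return EnrichmentCall(
        gene=profile.gene,
        ratio=ratio,
        ratio_unrounded=ratio_raw,
        fold_change=fold,
        fold_change_unrounded=fold_raw,
        enriched_tissue=enriched,
        low_expressed=all(v < low_threshold for v in values),
        high_expressed=all(v > high_threshold for v in values),
        linear_fold_t_over_ag=2.0 ** (t - ag),
    )


def prioritize(
    candidates: Iterable[str], calls: Sequence[EnrichmentCall]
) -> tuple[list[str], dict[str, str]]:
    """Keep testes-enriched candidates with unexceptional expression levels.

    Drops AG-enriched, unclassified (tied), lowly expressed (all tissue
    ΔCq < −10) and highly expressed (all tissue ΔCq > −5) genes.  Returns
    the prioritized genes (input order) and a per-gene drop reason map.
    """
    by_gene = {c.gene: c for c in calls}
    kept: list[str] = []
    reasons: dict[str, str] = {}
    for gene in candidates:
        call = by_gene.get(gene)
        if call is None:
            raise ValueError(f"candidate {gene} has no enrichment call")
        if call.low_expressed:
            reasons[gene] = "lowly expressed in all tissues (ΔCq < -10)"
        elif call.high_expressed:
            reasons[gene] = "highly expressed in all tissues (ΔCq > -5)"
        elif call.enriched_tissue == "AG":
            reasons[gene] = "accessory-gland enriched"
        elif call.enriched_tissue is None:
            reasons[gene] = "tissue enrichment unclassified (tied ΔCq)"
        else:
            kept.append(gene)
    return kept, reasons
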