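"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators mirror the three kinds of raw data the analysis consumes:

* per-replicate qPCR Cq tables whose group ΔCq means follow a configurable
  scenario (Gaussian cycle-scale noise, two reference genes separated by an
  additive offset),
* aligned interspecies sequence pairs with background substitutions, an
  optional planted cluster, optional single-base indels, and strain "reads"
  carrying shared-polymorphism evidence,
* overdispersed (negative-binomial; Poisson in the zero-dispersion limit)
  offspring counts per male class.

Every generator is deterministic given its scenario seed, and each returns
the ground truth needed for recovery testing alongside the artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .substitutions import Feature, SequencedFragment, SubstitutionEvent, _span_length

__all__ = [
    "ExpressionScenario",
    "SequenceScenario",
    "FecundityScenario",
    "SequenceSimulation",
    "generate_cq_table",
    "generate_sequence_pair",
    "generate_fecundity",
    "study_expression_scenario",
]

DEFAULT_REFERENCES = ("RpL32", "RpS18")
TISSUE_CLASSES = ("T", "SV", "AG", "EB")
READ_LENGTH = 100
_BASES = np.array(list("ACGT"))


@dataclass
class ExpressionScenario:
    """Target structure for a synthetic qPCR experiment.

    ``mean_dcq`` maps either ``(gene, sample_class)`` or
    ``(gene, sample_class, reference_gene)`` to the target ΔCq mean in
    cycles; two-key entries apply to the first reference gene, with
    ``reference_offset`` added for the second (ΔCq is consistently higher
    under the second reference, matching an additively shifted reference).
    ``replicate_sd`` is the within-group standard deviation of ΔCq.
    """

    genes: Sequence[str]
    sample_classes: Sequence[str]
    mean_dcq: Mapping[tuple, float]
    replicate_sd: float = 0.3
    n_replicates: int = 5
    reference_offset: float = 0.8
    references: tuple[str, str] = DEFAULT_REFERENCES
    reference_base_cq: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if not self.replicate_sd >= 0:
            raise ValueError("replicate_sd must be >= 0")
        if len(set(self.references)) != 2:
            raise ValueError("exactly two distinct reference genes required")
        for gene in self.genes:
            for cls in self.sample_classes:
                self.target_mean(gene, cls, self.references[0])

    def target_mean(self, gene: str, cls: str, reference: str) -> float:
        if (gene, cls, reference) in self.mean_dcq:
            return float(self.mean_dcq[(gene, cls, reference)])
        if (gene, cls) in self.mean_dcq:
            base = float(self.mean_dcq[(gene, cls)])
            return base + (self.reference_offset if reference == self.references[1] else 0.0)
        raise ValueError(f"no ΔCq mean configured for (gene, class) = ({gene}, {cls})")


def generate_cq_table(scenario: ExpressionScenario) -> pd.DataFrame:
    """Synthetic per-replicate Cq records.

    Reference and target Cq each receive independent Gaussian noise with
    sd ``replicate_sd/√2``, so ΔCq = Cq(ref) − Cq(target) has mean equal to
    the scenario mean and sd exactly ``replicate_sd``.  Deterministic given
    the scenario seed.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    sd = scenario.replicate_sd / np.sqrt(2.0)
    rows = []
    for gene in scenario.genes:
        for cls in scenario.sample_classes:
            for ref in scenario.references:
                m = scenario.target_mean(gene, cls, ref)
                noise = rng.normal(0.0, sd, size=(scenario.n_replicates, 2))
                for r in range(scenario.n_replicates):
                    cq_ref = scenario.reference_base_cq + noise[r, 0]
                    cq_tgt = scenario.reference_base_cq - m + noise[r, 1]
                    rows.append(
                        {
                            "gene": gene,
                            "sample_class": cls,
                            "tissue": cls if cls in TISSUE_CLASSES else "",
                            "replicate": f"rep{r + 1}",
                            "reference_gene": ref,
                            "cq_reference": cq_ref,
                            "cq_target": cq_tgt,
                        }
                    )
    return pd.DataFrame(rows)


@dataclass
class SequenceScenario:
    """Design of a synthetic aligned interspecies fragment.

    TSS-relative fragment with Bernoulli background substitutions, an
    optional planted cluster of extra events inside ``cluster_interval``,
    optional planted single-base deletions, and shared-polymorphism
    structure: a ``shared_polymorphism_rate`` fraction of differences also
    segregate among the reference-species strain reads.
    """

    gene: str = "synthetic"
    fragment_start: int = -1000
    fragment_end: int = 500
    background_rate: float = 0.002
    cluster_interval: tuple[int, int] | None = None
    cluster_extra_events: int = 0
    planted_indels: int = 0
    shared_polymorphism_rate: float = 0.0
    n_strain_reads: int = 3
    seed: int = 0

    def validate(self) -> None:
        if not self.fragment_start < 0 < self.fragment_end:
            raise ValueError("fragment must straddle the TSS (start < 0 < end)")
        for rate in (self.background_rate, self.shared_polymorphism_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.cluster_extra_events and self.cluster_interval is None:
            raise ValueError("cluster_extra_events requires a cluster_interval")
        if self.cluster_interval is not None:
            lo, hi = self.cluster_interval
            if not (self.fragment_start <= lo < hi <= self.fragment_end):
                raise ValueError("cluster_interval must lie within the fragment")

    @property
    def n_positions(self) -> int:
        return _span_length(self.fragment_start, self.fragment_end)


@dataclass
class SequenceSimulation:
    """Generator output: the aligned fragment, the planted truth, the reads."""

    fragment: SequencedFragment
    truth: list[SubstitutionEvent]
    reads: list[str]
    shared_positions: set[int] = field(default_factory=set)

    @property
    def fixed_truth(self) -> list[SubstitutionEvent]:
        return [ev for ev in self.truth if ev.fixed]


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(0, 3)]


def generate_sequence_pair(scenario: SequenceScenario) -> SequenceSimulation:
    """Simulate an aligned species pair plus strain-read polymorphism evidence.

    Differences are placed per-site Bernoulli(``background_rate``) plus
    ``cluster_extra_events`` extra events uniform inside the cluster
    interval.  Each difference is a shared polymorphism with probability
    ``shared_polymorphism_rate``, in which case the generated strain reads
    carry the alternate allele at that site.  Planted deletions are
    single-column gaps in species b.  The full truth (with ``fixed``
    resolved) is returned for recovery testing.  Deterministic given seed.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    L = scenario.n_positions
    seq_a = rng.choice(_BASES, size=L)

    diff_sites = set(np.flatnonzero(rng.random(L) < scenario.background_rate) + 1)
    if scenario.cluster_extra_events:
        lo_idx = _tss_idx(scenario, scenario.cluster_interval[0])
        hi_idx = _tss_idx(scenario, scenario.cluster_interval[1])
        available = [i for i in range(lo_idx, hi_idx + 1) if i not in diff_sites]
        if scenario.cluster_extra_events > len(available):
            raise ValueError(
                "cluster_extra_events exceeds the free positions in the cluster interval"
            )
        extra = rng.choice(len(available), size=scenario.cluster_extra_events, replace=False)
        diff_sites.update(available[i] for i in sorted(extra))

    indel_sites: list[int] = []
    if scenario.planted_indels:
        free = [i for i in range(1, L + 1) if i not in diff_sites]
        if scenario.planted_indels > len(free):
            raise ValueError("planted_indels exceeds the free positions")
        picks = rng.choice(len(free), size=scenario.planted_indels, replace=False)
        indel_sites = sorted(free[i] for i in picks)

    seq_b = seq_a.copy()
    truth: list[SubstitutionEvent] = []
    shared_positions: set[int] = set()
    all_events = sorted(
        [(i, "SNV") for i in diff_sites] + [(i, "deletion") for i in indel_sites]
    )
    for idx, kind in all_events:
        tss_pos = _idx_tss(scenario, idx)
        a_base = str(seq_a[idx - 1])
        if kind == "SNV":
            b_allele = _other_base(rng, a_base)
            seq_b[idx - 1] = b_allele
        else:
            b_allele = "-"
            seq_b[idx - 1] = "-"
        shared = bool(rng.random() < scenario.shared_polymorphism_rate)
        if shared:
            shared_positions.add(tss_pos)
        truth.append(
            SubstitutionEvent(
                gene=scenario.gene,
                tss_position=tss_pos,
                kind=kind,
                allele_a=a_base,
                allele_b=b_allele,
                fixed=not shared,
            )
        )

    fragment = SequencedFragment(
        gene=scenario.gene,
        tss_start=scenario.fragment_start,
        tss_end=scenario.fragment_end,
        seq_a="".join(seq_a),
        seq_b="".join(seq_b),
    )

    # strain reads: fixed-length windows of the species-a sequence around
    # each difference; at shared sites every read carries the species-b allele
    reads: list[str] = []
    ref = "".join(seq_a)
    for ev in truth:
        idx = _tss_idx(scenario, ev.tss_position)
        for _ in range(scenario.n_strain_reads):
            start = max(0, min(idx - 1 - READ_LENGTH // 2, L - READ_LENGTH))
            window = list(ref[start : start + READ_LENGTH])
            if ev.tss_position in shared_positions and ev.kind == "SNV":
                window[idx - 1 - start] = ev.allele_b
            reads.append("".join(window))

    return SequenceSimulation(
        fragment=fragment, truth=truth, reads=reads, shared_positions=shared_positions
    )


def _tss_idx(scenario: SequenceScenario, pos: int) -> int:
    from .substitutions import tss_to_index

    return tss_to_index(pos, scenario.fragment_start, scenario.fragment_end)


def _idx_tss(scenario: SequenceScenario, idx: int) -> int:
    from .substitutions import index_to_tss

    return index_to_tss(idx, scenario.fragment_start, scenario.fragment_end)


@dataclass
class FecundityScenario:
    """Offspring-count design: per-class means, replicate vials, dispersion.

    Counts are negative-binomial with variance ``m + dispersion * m^2``
    (Poisson at dispersion 0) — offspring counts are typically
    overdispersed.  Six vials per class matches the fecundity assay design.
    """

    classes: Sequence[str]
    mean_offspring: Mapping[str, float]
    n_vials: int = 6
    dispersion: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_vials < 2:
            raise ValueError("n_vials must be >= 2")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for cls in self.classes:
            if cls not in self.mean_offspring:
                raise ValueError(f"no mean offspring count for class {cls}")
            if self.mean_offspring[cls] < 0:
                raise ValueError(f"negative mean for class {cls}")


def generate_fecundity(scenario: FecundityScenario) -> pd.DataFrame:
    """Integer offspring counts per class × vial; deterministic given seed."""
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    rows = []
    for cls in scenario.classes:
        m = float(scenario.mean_offspring[cls])
        for v in range(scenario.n_vials):
            if m == 0:
                count = 0
            elif scenario.dispersion == 0:
                count = int(rng.poisson(m))
            else:
                lam = rng.gamma(shape=1.0 / scenario.dispersion, scale=m * scenario.dispersion)
                count = int(rng.poisson(lam))
            rows.append({"sample_class": cls, "vial": v + 1, "count": count})
    return pd.DataFrame(rows)


def study_expression_scenario(
    replicate_sd: float = 0.3, n_replicates: int = 5, seed: int = 0
) -> ExpressionScenario:
    """Scenario whose group means reproduce the published expression table.

    The published table prints no sterile-F1 means (those comparisons appear
    only graphically), so synthetic F1 means are placed to reproduce the
    reported misregulation structure: for each gene misregulated in fertile
    classes, the F1 mean equals the mean of its first flagged class (making
    that class F1-like); for genes never misregulated, the F1 mean sits far
    below every class mean so that incidental significance in the synthetic
    data cannot convert a retained gene into an excluded one.
    """
    from . import datasets
    from .candidates import FERTILE_CLASSES

    means: dict[tuple, float] = {}
    for gene in datasets.GENES:
        class_means = datasets.EXPRESSION_MEANS[gene]
        for cls, m in class_means.items():
            means[(gene, cls)] = m
        flagged = [c for c in FERTILE_CLASSES if (gene, c) in datasets.MISREGULATED]
        if flagged:
            means[(gene, datasets.STERILE_F1)] = class_means[flagged[0]]
        else:
            means[(gene, datasets.STERILE_F1)] = min(class_means.values()) - 6.0
    classes = list(datasets.SAMPLE_CLASSES) + [datasets.STERILE_F1]
    return ExpressionScenario(
        genes=list(datasets.GENES),
        sample_classes=classes,
        mean_dcq=means,
        replicate_sd=replicate_sd,
        n_replicates=n_replicates,
        seed=seed,
    )
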