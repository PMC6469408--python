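"""Readers and writers for the pipeline's plain-text interchange formats."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .hotspot import HotspotResult
from .substitutions import Feature, SequencedFragment, SubstitutionEvent

__all__ = [
    "read_cq_csv",
    "read_dilution_csv",
    "read_aligned_fasta",
    "write_aligned_fasta",
    "read_features_tsv",
    "read_evidence_tsv",
    "read_events_tsv",
    "write_events_tsv",
    "write_hotspot_tsv",
    "write_significance_json",
]


def read_cq_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"gene", "sample_class", "replicate", "reference_gene", "cq_reference", "cq_target"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing Cq columns {sorted(missing)}")
    return df


def read_dilution_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"log10_input", "cq"} <= set(df.columns):
        raise ValueError(f"{path}: dilution series needs columns log10_input, cq")
    return df


def read_aligned_fasta(
    path: str | Path, gene: str, tss_start: int, tss_end: int, features: Sequence[Feature] = ()
) -> SequencedFragment:
    """Two aligned records (species a first) -> a SequencedFragment."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"{path}: expected exactly 2 aligned records, got {len(records)}")
    return SequencedFragment(
        gene=gene,
        tss_start=tss_start,
        tss_end=tss_end,
        seq_a=str(records[0].seq),
        seq_b=str(records[1].seq),
        features=list(features),
    )


def write_aligned_fasta(path: str | Path, fragment: SequencedFragment, names=("species_a", "species_b")) -> None:
    records = [
        SeqRecord(Seq(fragment.seq_a), id=f"{fragment.gene}|{names[0]}", description=""),
        SeqRecord(Seq(fragment.seq_b), id=f"{fragment.gene}|{names[1]}", description=""),
    ]
    SeqIO.write(records, str(path), "fasta")


def read_features_tsv(path: str | Path) -> dict[str, list[Feature]]:
    """TSV with columns gene, feature_type, tss_start, tss_end."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[Feature]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["gene"]), []).append(
            Feature(str(row["feature_type"]), int(row["tss_start"]), int(row["tss_end"]))
        )
    return out


def read_evidence_tsv(path: str | Path) -> dict[int, set[str]]:
    """TSV with columns tss_position, alleles (comma-separated)."""
    df = pd.read_csv(path, sep="\t")
    return {
        int(row["tss_position"]): set(str(row["alleles"]).split(","))
        for _, row in df.iterrows()
    }


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "tss_position"} <= set(df.columns):
        raise ValueError(f"{path}: events table needs columns gene, tss_position")
    return df


def write_events_tsv(path: str | Path, events: Sequence[SubstitutionEvent]) -> None:
    rows = [
        {
            "gene": ev.gene,
            "tss_position": ev.tss_position,
            "kind": ev.kind,
            "domain": ev.domain if ev.domain is not None else "",
            "substitution": f"{ev.allele_a} > {ev.allele_b}",
            "fixed": ev.fixed,
        }
        for ev in events
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_hotspot_tsv(path: str | Path, results: Sequence[HotspotResult]) -> None:
    rows = [
        {
            "gene": r.gene,
            "region": r.region_label,
            "n": r.n_events,
            "N": r.length,
            "T": r.t_statistic,
            "hotspot_start": r.hotspot_interval[0],
            "hotspot_end": r.hotspot_interval[1],
            "events_in_hotspot": r.events_in_hotspot,
            "p_value": r.p_value,
            "q_value": r.q_value if r.q_value is not None else "",
            "n_sim": r.n_sim,
            "seed": r.seed if r.seed is not None else "",
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_significance_json(path: str | Path, reports) -> None:
    payload = {}
    for gene, rep in reports.items():
        payload[gene] = {
            "anova": {
                "F": rep.anova.f_statistic,
                "df": [rep.anova.df_num, rep.anova.df_den],
                "p": rep.anova.p_value,
            },
            "class_means": {k: float(v) for k, v in rep.class_means.items()},
            "pairwise_p": rep.pairwise.to_dict(),
            "qvalues": rep.qvalues.to_dict() if rep.qvalues is not None else None,
            "letters": rep.letters,
        }
    Path(path).write_text(json.dumps(payload, indent=2))
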