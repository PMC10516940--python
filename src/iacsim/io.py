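"""File formats and run reports.

Tables are tab-separated UTF-8 with ``#`` comment lines (class names may
contain commas, so TSV over CSV).  Cell tables carry one ``score_<class>``
column per classifier output class.  Genotype panels come from VCF (two
named sample columns; biallelic SNVs only) or from a plain dosage TSV.
Run configuration and reports round-trip through JSON with deterministic key
ordering; the report structure is validated against the JSON schema shipped
in ``iacsim/schemas/``.
"""

from __future__ import annotations

import json
import warnings
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .genotype import AlleleCounts, GenotypePanel, Variant
from .synth import CellRecord

__all__ = [
    "read_cell_table",
    "write_cell_table",
    "read_embeddings",
    "write_embeddings",
    "read_genotype_panel",
    "read_allele_counts",
    "RunConfig",
    "RunReport",
    "write_report",
    "read_report",
    "report_json_schema",
]

_RENORM_TOL = 1e-3
_ACCEPT_TOL = 1e-6


def write_cell_table(records: Sequence[CellRecord], path) -> None:
    """Write a cohort as TSV: cell_id, true_label, [arrival_time], score_<class>."""
    if not records:
        raise ValueError("cannot write an empty cohort")
    names = records[0].class_names
    rows = []
    has_time = records[0].arrival_time is not None
    for r in records:
        row = {"cell_id": r.cell_id, "true_label": r.true_label}
        if has_time:
            row["arrival_time"] = r.arrival_time
        row.update({f"score_{c}": s for c, s in zip(names, r.scores)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_cell_table(path) -> list[CellRecord]:
    """Read a cohort TSV, validating ids and score simplexes.

    Rows whose scores deviate from sum 1 by more than 1e-6 but at most 1e-3
    are renormalised with a warning; larger deviations are rejected.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("cell_id", "true_label"):
        if col not in df.columns:
            raise ValueError(f"cell table missing required column {col!r}")
    score_cols = [c for c in df.columns if c.startswith("score_")]
    if len(score_cols) < 2:
        raise ValueError("cell table needs at least two score_<class> columns")
    class_names = tuple(c[len("score_"):] for c in score_cols)
    dup = df["cell_id"].astype(str)[df["cell_id"].astype(str).duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate cell_id: {dup.iloc[0]!r}")
    scores = df[score_cols].to_numpy()
    if not np.issubdtype(scores.dtype, np.number) or np.isnan(scores).any():
        raise ValueError("non-numeric or missing score values")
    sums = scores.sum(axis=1)
    dev = np.abs(sums - 1.0)
    # boundary-inclusive: a deviation of exactly 1e-3 is still renormalised
    if (dev > _RENORM_TOL * (1 + 1e-9)).any():
        i = int(np.argmax(dev))
        raise ValueError(
            f"row {df['cell_id'].iloc[i]!r}: score sum {sums[i]:.6f} deviates "
            f"from 1 by more than {_RENORM_TOL}"
        )
    needs_renorm = dev > _ACCEPT_TOL
    if needs_renorm.any():
        warnings.warn(
            f"renormalised {int(needs_renorm.sum())} score row(s) deviating "
            f"from sum 1 by up to {dev.max():.2e}",
            stacklevel=2,
        )
    scores = scores / sums[:, None]
    times = df["arrival_time"].to_numpy(float) if "arrival_time" in df.columns else None
    if times is not None:
        if np.any(np.diff(times) <= 0):
            raise ValueError("arrival times must be strictly increasing")
    return [
        CellRecord(
            cell_id=str(df["cell_id"].iloc[i]),
            true_label=str(df["true_label"].iloc[i]),
            scores=scores[i],
            class_names=class_names,
            arrival_time=None if times is None else float(times[i]),
        )
        for i in range(len(df))
    ]


def write_embeddings(matrix: np.ndarray, path, binary: bool = False) -> None:
    """Write an n x d embedding matrix as TSV or a headered row-major binary."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("embeddings must be a 2-D matrix")
    path = Path(path)
    if binary:
        with open(path, "wb") as fh:
            fh.write(f"{X.shape[0]} {X.shape[1]}\n".encode())
            fh.write(X.astype("<f8").tobytes())
    else:
        np.savetxt(path, X, delimiter="\t")


def read_embeddings(path, binary: bool = False) -> np.ndarray:
    path = Path(path)
    if binary:
        with open(path, "rb") as fh:
            n, d = map(int, fh.readline().split())
            X = np.frombuffer(fh.read(), dtype="<f8").reshape(n, d)
        return X.copy()
    return np.atleast_2d(np.loadtxt(path, delimiter="\t"))


_GT_DOSAGE = {(0, 0): 0.0, (0, 1): 0.5, (1, 0): 0.5, (1, 1): 1.0}


def read_genotype_panel(
    path,
    target_sample: Optional[str] = None,
    background_sample: Optional[str] = None,
) -> GenotypePanel:
    """Read a genotype panel from VCF or dosage TSV.

    VCF: keeps biallelic SNVs only; GT 0/0, 0/1, 1/1 map to dosages 0, 0.5,
    1; multiallelic, indel, and incompletely genotyped records are skipped
    and counted in ``panel.n_skipped``.  TSV: columns variant_id, g_t, g_b
    (optionally chrom, pos, ref, alt).
    """
    path = Path(path)
    if path.suffix in (".vcf", ".gz", ".bcf"):
        if target_sample is None or background_sample is None:
            raise ValueError("VCF input requires target_sample and background_sample")
        return _read_panel_vcf(path, target_sample, background_sample)
    return _read_panel_tsv(path)


def _read_panel_vcf(path: Path, target: str, background: str) -> GenotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for name in (target, background):
        if name not in samples:
            raise ValueError(f"sample {name!r} not in VCF (has {samples})")
    i_t, i_b = samples.index(target), samples.index(background)
    variants, g_t, g_b = [], [], []
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            skipped += 1
            continue
        dosages = []
        for idx in (i_t, i_b):
            gt = rec.genotypes[idx]
            alleles = tuple(a for a in gt[:-1] if a is not None and a >= 0)
            if len(alleles) != 2 or any(a > 1 for a in alleles):
                dosages = None
                break
            dosages.append(_GT_DOSAGE[(alleles[0], alleles[1])])
        if dosages is None:
            skipped += 1
            continue
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}>{rec.ALT[0]}"
        variants.append(Variant(vid, rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        g_t.append(dosages[0])
        g_b.append(dosages[1])
    if skipped:
        warnings.warn(f"skipped {skipped} non-biallelic-SNV/incomplete VCF record(s)",
                      stacklevel=3)
    return GenotypePanel(
        variants=tuple(variants),
        target_dosage=np.array(g_t),
        background_dosage=np.array(g_b),
        n_skipped=skipped,
    )


def _read_panel_tsv(path: Path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("variant_id", "g_t", "g_b"):
        if col not in df.columns:
            raise ValueError(f"panel TSV missing required column {col!r}")
    variants = tuple(
        Variant(
            str(row["variant_id"]),
            str(row.get("chrom", ".")),
            int(row.get("pos", 0)),
            str(row.get("ref", "N")),
            str(row.get("alt", "N")),
        )
        for _, row in df.iterrows()
    )
    return GenotypePanel(
        variants=variants,
        target_dosage=df["g_t"].to_numpy(float),
        background_dosage=df["g_b"].to_numpy(float),
    )


def read_allele_counts(path) -> AlleleCounts:
    """Read per-variant ref/alt counts from TSV (variant_id, ref_count, alt_count)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("variant_id", "ref_count", "alt_count"):
        if col not in df.columns:
            raise ValueError(f"counts TSV missing required column {col!r}")
    return AlleleCounts(
        variant_ids=tuple(df["variant_id"].astype(str)),
        ref_count=df["ref_count"].to_numpy(),
        alt_count=df["alt_count"].to_numpy(),
    )


class RunConfig(BaseModel):
    """Flat key-value run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    subcommand: str
    params: dict[str, str | int | float | bool] = Field(default_factory=dict)
    seed: int = 0
    out_dir: Optional[str] = None
    format_version: str = "1"


class RunReport(BaseModel):
    """Structured output of one tool invocation."""

    model_config = ConfigDict(extra="forbid")

    config: RunConfig
    tool_version: str
    created: str  # ISO-8601 timestamp
    sort_report: Optional[dict] = None
    purity_estimate: Optional[dict] = None
    enrichment: Optional[dict] = None
    curve_summary: Optional[dict] = None
    outputs: dict[str, str] = Field(default_factory=dict)


def report_json_schema() -> dict:
    """The published JSON schema the shipped reports validate against."""
    with resources.files("iacsim.schemas").joinpath("run_report.schema.json").open() as fh:
        return json.load(fh)


def write_report(report: RunReport, path) -> None:
    """Serialise a validated report with deterministic key ordering."""
    RunReport.model_validate(report.model_dump())  # reject malformed structures
    text = json.dumps(report.model_dump(), sort_keys=True, indent=2)
    Path(path).write_text(text + "\n")


def read_report(path) -> RunReport:
    return RunReport.model_validate_json(Path(path).read_text())
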