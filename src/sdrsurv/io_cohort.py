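"""Cohort input/output: genotype and survival tables, SNP metadata, report writing.

The canonical on-disk dialect is TSV (UTF-8, header required):

* genotypes — ``subject_id`` column plus one column per SNP, cells are
  unordered diploid allele pairs (``"AG"``; ``"./."``, ``"NA"`` or empty for
  missing);
* survival — ``subject_id``, ``time_months``, ``event`` plus optional
  numeric covariate columns.

A thin VCF reader (biallelic sites, GT field) is provided for convenience.
Genotype strings are unordered (``"AG"`` == ``"GA"``) and are normalized to
major-allele-first internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING_TOKENS = {"", ".", "..", "./.", ".|.", "NA", "nan", "NaN"}

#: integer genotype codes: 0 = homozygous major, 1 = het, 2 = homozygous minor
MISSING_CODE = -1


class CohortValidationError(ValueError):
    """Raised when an input table violates the cohort contracts."""


@dataclass(frozen=True)
class SnpDef:
    """Definition of one biallelic SNP in the panel."""

    snp_id: str
    gene: str = ""
    assay_id: str | None = None
    allele_major: str = ""
    allele_minor: str = ""

    def __post_init__(self) -> None:
        if self.allele_major and self.allele_major == self.allele_minor:
            raise CohortValidationError(
                f"{self.snp_id}: major and minor allele must differ"
            )

    def genotype_string(self, code: int) -> str:
        """Return the normalized genotype string for an integer code."""
        if code == 0:
            return self.allele_major * 2
        if code == 1:
            # heterozygotes are conventionally printed alphabetically
            a, b = sorted((self.allele_major, self.allele_minor))
            return a + b
        if code == 2:
            return self.allele_minor * 2
        return "./."


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs diploid genotype calls.

    ``codes`` holds integer codes (0 hom-major, 1 het, 2 hom-minor,
    -1 missing), shape (n_subjects, n_snps).
    """

    subject_ids: list[str]
    panel: list[SnpDef]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        n, p = self.codes.shape
        if n != len(self.subject_ids) or p != len(self.panel):
            raise CohortValidationError("codes shape inconsistent with ids/panel")
        if n < 1 or p < 1:
            raise CohortValidationError("need at least one subject and one SNP")
        if len(set(self.subject_ids)) != n:
            raise CohortValidationError("duplicate subject_id")
        if len({s.snp_id for s in self.panel}) != p:
            raise CohortValidationError("duplicate snp_id in panel")

    @property
    def n_subjects(self) -> int:
        return self.codes.shape[0]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.panel]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"SNP {snp_id!r} not in panel") from None

    def genotype_counts(self, snp_id: str) -> tuple[int, int, int]:
        """(hom-major, het, hom-minor) tallies over non-missing calls."""
        col = self.codes[:, self.snp_index(snp_id)]
        return (int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))

    def to_frame(self) -> pd.DataFrame:
        """String-genotype DataFrame in the canonical TSV layout."""
        data = {}
        for j, snp in enumerate(self.panel):
            data[snp.snp_id] = [snp.genotype_string(c) for c in self.codes[:, j]]
        return pd.DataFrame(data, index=pd.Index(self.subject_ids, name="subject_id"))

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", lineterminator="\n")


@dataclass
class SurvivalOutcome:
    """Right-censored survival times (months) with optional clinical covariates."""

    subject_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.subject_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise CohortValidationError("time/event length mismatch with subject_ids")
        if not np.all(np.isfinite(self.time)) or np.any(self.time <= 0):
            bad = [self.subject_ids[i] for i in np.where(~(self.time > 0))[0][:5]]
            raise CohortValidationError(f"non-positive or non-finite time for {bad}")
        if not np.isin(self.event, (0, 1)).all():
            raise CohortValidationError("event indicator must be 0 or 1")
        if self.covariates is not None and len(self.covariates) != n:
            raise CohortValidationError("covariate rows mismatch subject_ids")

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"time_months": self.time, "event": self.event},
            index=pd.Index(self.subject_ids, name="subject_id"),
        )
        if self.covariates is not None:
            cov = self.covariates.copy()
            cov.index = df.index
            df = pd.concat([df, cov], axis=1)
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", lineterminator="\n")

    def subset(self, idx: np.ndarray) -> "SurvivalOutcome":
        cov = None
        if self.covariates is not None:
            cov = self.covariates.iloc[idx].reset_index(drop=True)
        return SurvivalOutcome(
            [self.subject_ids[i] for i in idx], self.time[idx], self.event[idx], cov
        )


@dataclass
class ReportBundle:
    """Named output tables, each serializable to TSV and JSON with stable columns."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def add(self, name: str, table: pd.DataFrame) -> None:
        self.tables[name] = table


def _infer_alleles(column: pd.Series, snp_id: str) -> tuple[str, str]:
    """Major/minor alleles from observed calls; ties break to the
    lexicographically smaller allele as major."""
    counts: dict[str, int] = {}
    for subj, cell in column.items():
        for ch in cell:
            counts[ch] = counts.get(ch, 0) + 1
    alleles = sorted(counts)
    if len(alleles) > 2:
        # keep the two most frequent; the per-cell validator then names the
        # offending subject/call for anything using a third allele
        alleles = sorted(sorted(counts, key=lambda a: -counts[a])[:2])
    if len(alleles) == 1:
        # monomorphic: synthesize a placeholder minor allele
        a = alleles[0]
        minor = "N" if a != "N" else "M"
        return a, minor
    a, b = alleles
    if counts[a] > counts[b]:
        return a, b
    if counts[b] > counts[a]:
        return b, a
    return a, b  # tie -> lexicographic smaller is major


def _encode_column(
    column: pd.Series, snp: SnpDef
) -> np.ndarray:
    codes = np.empty(len(column), dtype=np.int8)
    valid = {snp.allele_major, snp.allele_minor}
    for i, (subj, cell) in enumerate(column.items()):
        if cell is None:
            codes[i] = MISSING_CODE
            continue
        cell = str(cell).strip()
        if cell in MISSING_TOKENS:
            codes[i] = MISSING_CODE
            continue
        if len(cell) != 2 or not set(cell) <= valid:
            raise CohortValidationError(
                f"subject {subj!r}, SNP {snp.snp_id}: invalid call {cell!r} "
                f"(alleles {snp.allele_major}/{snp.allele_minor})"
            )
        codes[i] = (cell[0] == snp.allele_minor) + (cell[1] == snp.allele_minor)
    return codes


def read_genotypes(
    path: str | Path,
    format: str = "tsv",
    panel: list[SnpDef] | None = None,
) -> GenotypeMatrix:
    """Read and validate a genotype table.

    Parameters
    ----------
    path
        Input file.
    format
        ``"tsv"`` (canonical dialect) or ``"vcf"`` (biallelic sites, GT field).
    panel
        Optional pre-declared SNP definitions. When omitted, major/minor
        alleles are inferred from observed allele frequencies (ties resolved
        to the lexicographically smaller allele as major).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path)
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "subject_id":
        raise CohortValidationError("first column must be 'subject_id'")
    subject_ids = df["subject_id"].tolist()
    if len(set(subject_ids)) != len(subject_ids):
        dupes = df["subject_id"][df["subject_id"].duplicated()].tolist()
        raise CohortValidationError(f"duplicate subject_id: {dupes}")
    df = df.set_index("subject_id")

    by_id = {s.snp_id: s for s in panel} if panel else {}
    snps: list[SnpDef] = []
    cols = []
    for snp_id in df.columns:
        column = df[snp_id]
        if snp_id in by_id:
            snp = by_id[snp_id]
        else:
            nonmiss = column[~column.str.strip().isin(MISSING_TOKENS)]
            major, minor = _infer_alleles(nonmiss, snp_id)
            snp = SnpDef(snp_id=snp_id, allele_major=major, allele_minor=minor)
        snps.append(snp)
        cols.append(_encode_column(column, snp))
    return GenotypeMatrix(subject_ids, snps, np.column_stack(cols))


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subject_ids = list(vcf.samples)
    snps: list[SnpDef] = []
    cols: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            raise CohortValidationError(
                f"non-biallelic-SNV record at {var.CHROM}:{var.POS} ({var.ID})"
            )
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        # alt-allele dosage per subject; -1 for missing
        alt_codes = np.array(
            [-1 if g[0] < 0 or g[1] < 0 else g[0] + g[1] for g in var.genotypes],
            dtype=np.int8,
        )
        obs = alt_codes[alt_codes >= 0]
        alt_freq = obs.sum() / (2 * len(obs)) if len(obs) else 0.0
        ref, alt = var.REF, var.ALT[0]
        if alt_freq > 0.5 or (alt_freq == 0.5 and alt < ref):
            major, minor = alt, ref
            codes = np.where(alt_codes >= 0, 2 - alt_codes, MISSING_CODE)
        else:
            major, minor = ref, alt
            codes = alt_codes
        snps.append(SnpDef(snp_id=snp_id, allele_major=major, allele_minor=minor))
        cols.append(codes.astype(np.int8))
    return GenotypeMatrix(subject_ids, snps, np.column_stack(cols))


def read_survival(path: str | Path) -> SurvivalOutcome:
    """Read and validate a survival TSV (subject_id, time_months, event, covariates)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    required = {"subject_id", "time_months", "event"}
    if not required <= set(df.columns):
        raise CohortValidationError(f"survival table needs columns {sorted(required)}")
    cov_cols = [c for c in df.columns if c not in required]
    covariates = df[cov_cols].reset_index(drop=True) if cov_cols else None
    return SurvivalOutcome(
        df["subject_id"].astype(str).tolist(),
        df["time_months"].to_numpy(float),
        df["event"].to_numpy(),
        covariates,
    )


def join_cohort(
    gm: GenotypeMatrix, outcome: SurvivalOutcome
) -> tuple[GenotypeMatrix, SurvivalOutcome]:
    """Align genotypes and survival on subject_id (survival order).

    Every survival subject must be genotyped; unmatched ids are rejected.
    """
    pos = {s: i for i, s in enumerate(gm.subject_ids)}
    missing = [s for s in outcome.subject_ids if s not in pos]
    if missing:
        raise CohortValidationError(
            f"{len(missing)} survival subject(s) absent from genotypes: {missing[:10]}"
        )
    idx = np.array([pos[s] for s in outcome.subject_ids])
    gm2 = GenotypeMatrix(list(outcome.subject_ids), gm.panel, gm.codes[idx])
    return gm2, outcome


def write_reports(bundle: ReportBundle, outdir: str | Path) -> list[str]:
    """Write each bundle table as a TSV/JSON twin; return the file manifest.

    File names and bytes are deterministic under fixed input.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    for name in sorted(bundle.tables):
        table = bundle.tables[name]
        tsv = outdir / f"{name}.tsv"
        table.to_csv(tsv, sep="\t", index=False, lineterminator="\n")
        js = outdir / f"{name}.json"
        records = json.loads(table.to_json(orient="records"))
        js.write_text(json.dumps(records, indent=1, sort_keys=False) + "\n")
        manifest.extend([tsv.name, js.name])
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest
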