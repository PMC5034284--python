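"""Readers, writers and domain containers for every table the pipeline touches.

All tabular formats are plain TSV with a header row; gene sets are GMT and
CpG positions are BED6+1 (0-based, half-open).  Readers validate the type
invariants up front and raise :class:`ParseError` / :class:`ValidationError`
with the offending location — no silent coercion.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("proteoscope")

SCALE_RPKM = "rpkm"
SCALE_LOG10P = "log10p"  # log10(1000 * RPKM + 1)

#: catalytic subunits of the constitutive proteasome
CP_GENES = ("PSMB5", "PSMB6", "PSMB7")
#: IFN-gamma-inducible catalytic subunits of the immunoproteasome
IP_GENES = ("PSMB8", "PSMB9", "PSMB10")
#: PA28 regulatory-cap subunits, co-regulated with the IP
REGULATORY_GENES = ("PSME1", "PSME2")
#: transcript proxies for tumour-infiltrating lymphocytes / IFN signalling
MARKER_GENES = ("CD3E", "CD8A", "PRF1", "IFNG", "EMR1")


class ParseError(ValueError):
    """A file could not be parsed as its declared format."""


class ValidationError(ValueError):
    """A parsed object violates a domain-type invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene x sample expression with an explicit scale tag.

    ``values`` is a DataFrame indexed by gene symbol with sample columns.
    ``scale`` is ``"rpkm"`` (raw, non-negative) or ``"log10p"``
    (``log10(1000 * RPKM + 1)``, also non-negative).
    """

    values: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in (SCALE_RPKM, SCALE_LOG10P):
            raise ValidationError(f"unknown scale {self.scale!r}")
        idx = self.values.index
        if idx.duplicated().any():
            dups = sorted(set(idx[idx.duplicated()]))
            raise ValidationError(f"duplicate gene ids: {dups}")
        cols = self.values.columns
        if cols.duplicated().any():
            dups = sorted(set(cols[cols.duplicated()]))
            raise ValidationError(f"duplicate sample ids: {dups}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("expression values must be finite")
        if (arr < 0).any():
            raise ValidationError(f"negative values not allowed on scale {self.scale}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise ValidationError(f"genes absent from matrix: {missing}")
        return ExpressionMatrix(self.values.loc[list(genes)], self.scale)


@dataclass
class ClinicalTable:
    """Per-sample vital status, follow-up times and categorical labels.

    Missing days are ``NaN`` (never sentinel numbers).  ``labels`` maps a
    label name (e.g. ``"FAB"``) to a sample -> value Series.
    """

    sample_ids: list[str]
    vital_status: pd.Series  # "expired" | "living"
    days_to_death: pd.Series  # float days, NaN if missing
    days_to_last_followup: pd.Series
    labels: dict[str, pd.Series] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids in clinical table")
        bad = set(self.vital_status.unique()) - {"expired", "living"}
        if bad:
            raise ValidationError(f"vital_status values outside expired/living: {sorted(bad)}")
        for name, s in (("days_to_death", self.days_to_death),
                        ("days_to_last_followup", self.days_to_last_followup)):
            if (s.dropna() < 0).any():
                raise ValidationError(f"{name} contains negative days")
        expired = self.vital_status == "expired"
        if self.days_to_death[expired].isna().any():
            missing = list(self.days_to_death[expired].index[self.days_to_death[expired].isna()])
            raise ValidationError(f"expired samples missing days_to_death: {missing}")
        living = self.vital_status == "living"
        if self.days_to_last_followup[living].isna().any():
            missing = list(
                self.days_to_last_followup[living].index[self.days_to_last_followup[living].isna()]
            )
            raise ValidationError(f"living samples missing days_to_last_followup: {missing}")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "vital_status": self.vital_status,
                "days_to_death": self.days_to_death,
                "days_to_last_followup": self.days_to_last_followup,
            },
            index=pd.Index(self.sample_ids, name="sample_id"),
        )
        for name, s in self.labels.items():
            df[name] = s
        return df


@dataclass
class MethylationMatrix:
    """CpG x sample beta values, each in [0, 1] or missing."""

    beta_values: pd.DataFrame  # index cpg_id, columns sample_id

    def __post_init__(self) -> None:
        idx = self.beta_values.index
        if idx.duplicated().any():
            raise ValidationError(f"duplicate cpg ids: {sorted(set(idx[idx.duplicated()]))}")
        arr = self.beta_values.to_numpy(dtype=float)
        finite = np.isfinite(arr)
        if ((arr[finite] < 0) | (arr[finite] > 1)).any():
            raise ValidationError("beta values must lie in [0, 1]")

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.beta_values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta_values.columns)


@dataclass(frozen=True)
class CpGAnnotation:
    """A CpG site annotated to a transcript TSS.

    ``signed_distance`` is negative when the site lies upstream of the TSS
    with respect to the transcript strand: on ``+`` it is ``position -
    tss_position``, on ``-`` it is ``tss_position - position``.
    """

    cpg_id: str
    chromosome: str
    position: int  # 0-based bp
    gene_id: str
    tss_position: int  # 0-based bp
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.cpg_id}: strand must be + or -, got {self.strand!r}")
        if self.position < 0 or self.tss_position < 0:
            raise ValidationError(f"{self.cpg_id}: positions must be >= 0")

    @property
    def signed_distance(self) -> int:
        d = self.position - self.tss_position
        return d if self.strand == "+" else -d


@dataclass
class GeneSetCollection:
    """term_id -> (term_name, frozenset of gene symbols), plus optional universe."""

    sets: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for term, (_, genes) in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {term} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def genes(self, term: str) -> frozenset[str]:
        return self.sets[term][1]


@dataclass
class DrugResponseTable:
    """One log-IC50 record per (cell line, drug)."""

    records: pd.DataFrame  # columns cell_line_id, drug_name, log_ic50

    def __post_init__(self) -> None:
        required = {"cell_line_id", "drug_name", "log_ic50"}
        if not required <= set(self.records.columns):
            raise ValidationError(f"drug table needs columns {sorted(required)}")
        if self.records.duplicated(["cell_line_id", "drug_name"]).any():
            raise ValidationError("duplicate (cell_line, drug) records")
        if not np.isfinite(self.records["log_ic50"].to_numpy(dtype=float)).all():
            raise ValidationError("log_ic50 must be finite")

    def for_drug(self, drug: str) -> pd.Series:
        sub = self.records[self.records["drug_name"] == drug]
        return sub.set_index("cell_line_id")["log_ic50"]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_expression(path: str | Path, scale: str = SCALE_RPKM) -> ExpressionMatrix:
    """Read a gene x sample TSV (gene rows, sample columns, header row)."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
    if not header.strip():
        raise ParseError(f"{path}: empty file or blank header line 1")
    fields = header.rstrip("\n").split("\t")
    if len(fields) < 2:
        raise ParseError(f"{path}: header line 1 has no sample columns")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValidationError(f"{path}: duplicated gene rows: {dups}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric expression value ({exc})") from exc
    mat = ExpressionMatrix(df, scale)
    logger.info("read_expression: %s -> %d genes x %d samples (scale=%s)",
                path, mat.n_genes, mat.n_samples, scale)
    return mat


def write_expression(mat: ExpressionMatrix, path: str | Path) -> None:
    mat.values.to_csv(path, sep="\t", index_label="gene_id")


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    required = {"vital_status", "days_to_death", "days_to_last_followup"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing clinical columns {sorted(missing)}")
    labels = {
        c: df[c].astype(str)
        for c in df.columns
        if c not in required
    }
    return ClinicalTable(
        sample_ids=list(df.index.astype(str)),
        vital_status=df["vital_status"],
        days_to_death=pd.to_numeric(df["days_to_death"], errors="coerce"),
        days_to_last_followup=pd.to_numeric(df["days_to_last_followup"], errors="coerce"),
        labels=labels,
    )


def write_clinical(tab: ClinicalTable, path: str | Path) -> None:
    tab.to_frame().to_csv(path, sep="\t")


def read_methylation(path: str | Path) -> MethylationMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return MethylationMatrix(df.astype(float))


def write_methylation(meth: MethylationMatrix, path: str | Path) -> None:
    meth.beta_values.to_csv(path, sep="\t", index_label="cpg_id")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: term, description, then tab-separated gene symbols."""
    path = Path(path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has < 3 fields")
            term, desc, genes = fields[0], fields[1], fields[2:]
            if term in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate term id {term}")
            genes = [g for g in genes if g]
            if len(set(genes)) != len(genes):
                raise ValidationError(f"{path}:{lineno}: duplicate genes within set {term}")
            sets[term] = (desc, frozenset(genes))
    return GeneSetCollection(sets)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for term, (desc, genes) in coll.sets.items():
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


def read_cpg_bed(path: str | Path) -> list[CpGAnnotation]:
    """Read a BED6+1 of CpG sites: chrom, start, end, cpg_id, gene_id, strand, tss.

    Coordinates are 0-based half-open; ``start`` is taken as the CpG position.
    """
    path = Path(path)
    out: list[CpGAnnotation] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ParseError(f"{path}:{lineno}: expected 7 BED columns, got {len(fields)}")
            chrom, start, _end, cpg_id, gene_id, strand, tss = fields[:7]
            try:
                start_i, tss_i = int(start), int(tss)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            out.append(
                CpGAnnotation(
                    cpg_id=cpg_id, chromosome=chrom, position=start_i,
                    gene_id=gene_id, tss_position=tss_i, strand=strand,
                )
            )
    seen: set[str] = set()
    for a in out:
        if a.cpg_id in seen:
            raise ValidationError(f"{path}: duplicate cpg_id {a.cpg_id}")
        seen.add(a.cpg_id)
    return out


def write_cpg_bed(annots: Iterable[CpGAnnotation], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for a in annots:
            fh.write(
                "\t".join(
                    [a.chromosome, str(a.position), str(a.position + 1),
                     a.cpg_id, a.gene_id, a.strand, str(a.tss_position)]
                )
                + "\n"
            )


def read_drug_response(path: str | Path) -> DrugResponseTable:
    df = pd.read_csv(path, sep="\t")
    return DrugResponseTable(df)


def write_drug_response(tab: DrugResponseTable, path: str | Path) -> None:
    tab.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# configuration and run manifest
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict[str, dict[str, object]] = {
    "scoring": {"cp_genes": list(CP_GENES), "ip_genes": list(IP_GENES),
                "decile_pct": 0.10},
    "survival": {"pairwise_correction": "bonferroni", "tie_method": "efron"},
    "structure": {"linkage": "complete", "n_clusters": 5,
                  "r_meth": 0.2, "window_bp": 10000},
    "conet": {"centile": 0.01, "alpha": 0.05, "align_rule": "similar",
              "kappa": 1.0, "t0": 1.0, "cooling": 0.99,
              "sweeps_per_temp": 20, "t_min": 1e-3},
    "enrichment": {"or_min": 2.0, "q_max": 0.05},
}


def load_config(path: str | Path | None = None) -> dict[str, dict[str, object]]:
    """Load a TOML config (one namespace per pipeline stage) over the defaults."""
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with Path(path).open("rb") as fh:
            user = tomllib.load(fh)
        for section, values in user.items():
            cfg.setdefault(section, {}).update(values)
    return cfg


def write_manifest(path: str | Path, *, config: Mapping, seed: int | None,
                   extra: Mapping | None = None) -> None:
    """Record config, seed and key library versions for a run."""
    import lifelines
    import scipy

    manifest = {
        "config": {k: dict(v) for k, v in config.items()},
        "seed": seed,
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "lifelines": lifelines.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
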