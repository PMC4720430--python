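"""Domain types and file I/O for the confounder-diagnostic pipeline.

The pipeline operates on an already-normalized log2 expression matrix
(genes x samples), a sample metadata table describing the repeated-biopsy
design (individual, series, recovery time, dose arm, treated flag), and
named gene sets.  Formats are plain text: TSV for matrices and metadata,
GMT for gene sets, YAML for run configuration.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "ValidationError",
    "ConfigError",
    "Series",
    "Dose",
    "Provenance",
    "ExpressionMatrix",
    "SampleRecord",
    "SampleTable",
    "GeneSet",
    "PipelineConfig",
    "EARLY_TIMES",
    "LATE_TIMES",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_table",
    "write_sample_table",
    "read_gene_sets",
    "write_gene_sets",
    "load_config",
    "setup_logging",
]

log = logging.getLogger("confounderscan")

#: Recovery-time grids (hours) of the two biopsy series.
EARLY_TIMES: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)
LATE_TIMES: tuple[float, ...] = (0.0, 7.5, 9.0, 10.5, 12.0)

#: Recovery time -> biopsy order.  The late sequence restarts at 7.5 h (the
#: mouse is assumed recovered from its t0 biopsy by then), so both t0 and
#: t7.5 carry biopsy order 1.
EARLY_BIOPSY_MAP: dict[float, int] = {0.0: 1, 1.0: 2, 2.0: 3, 3.0: 4, 4.0: 5, 5.0: 6}
LATE_BIOPSY_MAP: dict[float, int] = {0.0: 1, 7.5: 1, 9.0: 2, 10.5: 3, 12.0: 4}


class FormatError(ValueError):
    """Malformed input file (ragged rows, duplicate IDs, non-numeric cells)."""


class ValidationError(ValueError):
    """Record violating a domain constraint of the experimental design."""


class ConfigError(ValueError):
    """Inconsistent run or simulation configuration."""


class Series(str, Enum):
    EARLY = "early"
    LATE = "late"

    @property
    def times(self) -> tuple[float, ...]:
        return EARLY_TIMES if self is Series.EARLY else LATE_TIMES


class Dose(str, Enum):
    NONE = "none"
    LOW = "low"
    HIGH = "high"


class Provenance(str, Enum):
    SC = "SC"          # sample composition
    TD = "TD"          # time of day
    HS = "HS"          # handling / biopsy stress
    IM = "IM"          # individual effect
    DEG = "DEG"
    TRUTH = "truth"
    OTHER = "other"


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """log2 expression values, genes x samples."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"value matrix shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for kind, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise FormatError(f"duplicate {kind} ID {dup!r}")
        if not np.all(np.isfinite(self.values)):
            g, s = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._sample_index = {s: j for j, s in enumerate(self.sample_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_rows(self, genes: Sequence[str]) -> np.ndarray:
        try:
            idx = [self._gene_index[g] for g in genes]
        except KeyError as e:
            raise KeyError(f"gene {e.args[0]!r} not in matrix") from None
        return self.values[idx, :]

    def sample_cols(self, samples: Sequence[str]) -> np.ndarray:
        try:
            idx = [self._sample_index[s] for s in samples]
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} not in matrix") from None
        return self.values[:, idx]

    def subset(self, genes: Optional[Sequence[str]] = None,
               samples: Optional[Sequence[str]] = None) -> "ExpressionMatrix":
        genes = list(genes) if genes is not None else self.gene_ids
        samples = list(samples) if samples is not None else self.sample_ids
        vals = self.gene_rows(genes)[:, [self._sample_index[s] for s in samples]]
        return ExpressionMatrix(list(genes), list(samples), vals.copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def _first_duplicate(ids: Iterable[str]) -> Optional[str]:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes-x-samples TSV: header row of sample IDs, first column gene IDs."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty file")
        sample_ids = header.split("\t")[1:]
        if not sample_ids:
            raise FormatError(f"{path}: header has no sample IDs")
        gene_ids: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(sample_ids) + 1:
                raise FormatError(
                    f"{path}:{lineno}: ragged row ({len(fields)} fields, "
                    f"expected {len(sample_ids) + 1})"
                )
            gene_ids.append(fields[0])
            try:
                rows.append(np.array([float(x) for x in fields[1:]]))
            except ValueError:
                for col, x in enumerate(fields[1:], start=1):
                    try:
                        float(x)
                    except ValueError:
                        raise FormatError(
                            f"{path}:{lineno}: non-numeric cell {x!r} in column "
                            f"{col} (sample {sample_ids[col - 1]!r})"
                        ) from None
                raise
    if not gene_ids:
        raise FormatError(f"{path}: no gene rows")
    return ExpressionMatrix(gene_ids, sample_ids, np.vstack(rows))


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


# ---------------------------------------------------------------------------
# sample table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    individual_id: str
    series: Series
    recovery_time_h: float
    dose: Dose
    treated: bool
    biopsy_order: Optional[int] = None

    def __post_init__(self) -> None:
        if self.recovery_time_h < 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: negative recovery time")
        if self.recovery_time_h not in self.series.times:
            raise ValidationError(
                f"sample {self.sample_id!r}: recovery time {self.recovery_time_h} h "
                f"not in the {self.series.value} grid {self.series.times}"
            )
        if self.biopsy_order is not None and not 1 <= self.biopsy_order <= 6:
            raise ValidationError(
                f"sample {self.sample_id!r}: biopsy order {self.biopsy_order} "
                "outside 1..6"
            )


@dataclass
class SampleTable:
    records: list[SampleRecord]

    def __post_init__(self) -> None:
        dup = _first_duplicate(r.sample_id for r in self.records)
        if dup is not None:
            raise ValidationError(f"duplicate sample ID {dup!r}")
        per_ind: dict[str, tuple[Series, Dose]] = {}
        for r in self.records:
            key = (r.series, r.dose)
            prev = per_ind.setdefault(r.individual_id, key)
            if prev != key:
                raise ValidationError(
                    f"individual {r.individual_id!r} spans two design arms: "
                    f"({prev[0].value},{prev[1].value}) and "
                    f"({key[0].value},{key[1].value})"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    @property
    def individual_ids(self) -> list[str]:
        out, seen = [], set()
        for r in self.records:
            if r.individual_id not in seen:
                seen.add(r.individual_id)
                out.append(r.individual_id)
        return out

    def by_individual(self) -> dict[str, list[SampleRecord]]:
        out: dict[str, list[SampleRecord]] = {}
        for r in self.records:
            out.setdefault(r.individual_id, []).append(r)
        return out

    def filter(self, *, series: Optional[Series] = None,
               treated: Optional[bool] = None,
               dose: Optional[Dose] = None,
               individuals: Optional[Iterable[str]] = None) -> "SampleTable":
        inds = set(individuals) if individuals is not None else None
        recs = [
            r for r in self.records
            if (series is None or r.series == series)
            and (treated is None or r.treated == treated)
            and (dose is None or r.dose == dose)
            and (inds is None or r.individual_id in inds)
        ]
        return SampleTable(recs)

    def record_for(self, sample_id: str) -> SampleRecord:
        for r in self.records:
            if r.sample_id == sample_id:
                return r
        raise KeyError(sample_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in self.records],
                "individual_id": [r.individual_id for r in self.records],
                "series": [r.series.value for r in self.records],
                "recovery_time_h": [r.recovery_time_h for r in self.records],
                "dose": [r.dose.value for r in self.records],
                "treated": [int(r.treated) for r in self.records],
                "biopsy_order": [
                    "" if r.biopsy_order is None else r.biopsy_order
                    for r in self.records
                ],
            }
        )


_REQUIRED_SAMPLE_COLS = (
    "sample_id", "individual_id", "series", "recovery_time_h", "dose", "treated",
)

_TRUTHY = {"1", "true", "yes"}
_FALSY = {"0", "false", "no"}


def read_sample_table(path: str | Path) -> SampleTable:
    """Read sample metadata TSV; biopsy_order is assigned later by relabeling."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_SAMPLE_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise FormatError(f"{path}: no records")
    records = []
    for _, row in df.iterrows():
        treated_raw = row["treated"].strip().lower()
        if treated_raw in _TRUTHY:
            treated = True
        elif treated_raw in _FALSY:
            treated = False
        else:
            raise FormatError(
                f"{path}: sample {row['sample_id']!r}: unrecognized treated "
                f"flag {row['treated']!r}"
            )
        try:
            series = Series(row["series"].strip().lower())
            dose = Dose(row["dose"].strip().lower())
        except ValueError as e:
            raise ValidationError(f"{path}: sample {row['sample_id']!r}: {e}") from None
        try:
            t = float(row["recovery_time_h"])
        except ValueError:
            raise FormatError(
                f"{path}: sample {row['sample_id']!r}: non-numeric recovery "
                f"time {row['recovery_time_h']!r}"
            ) from None
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                individual_id=row["individual_id"],
                series=series,
                recovery_time_h=t,
                dose=dose,
                treated=treated,
            )
        )
    return SampleTable(records)


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT dialect)
# ---------------------------------------------------------------------------

@dataclass
class GeneSet:
    """A named gene list with a provenance label.

    ``genes`` preserves insertion order (needed for stable GMT round-trips)
    while membership tests are O(1).
    """

    name: str
    provenance: Provenance
    genes: tuple[str, ...]
    description: str = ""
    empty_allowed: bool = False
    oversize: bool = False

    def __post_init__(self) -> None:
        self.genes = tuple(dict.fromkeys(self.genes))
        if not self.genes and not self.empty_allowed:
            raise ValidationError(f"gene set {self.name!r} is empty")
        self._members = frozenset(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self._members

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def members(self) -> frozenset[str]:
        return self._members


def write_gene_sets(sets: Sequence[GeneSet], path: str | Path) -> None:
    """Write GMT: name TAB description TAB gene1 TAB gene2 ..., one line per set."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for gs in sets:
            if not gs.genes and not gs.empty_allowed:
                raise ValidationError(f"refusing to write empty gene set {gs.name!r}")
            desc = gs.description or gs.provenance.value
            fh.write("\t".join([gs.name, desc, *gs.genes]) + "\n")


def read_gene_sets(path: str | Path,
                   provenance: Provenance = Provenance.OTHER) -> list[GeneSet]:
    out = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line with <3 fields")
            out.append(
                GeneSet(
                    name=fields[0],
                    provenance=provenance,
                    genes=tuple(fields[2:]),
                    description=fields[1],
                )
            )
    return out


# ---------------------------------------------------------------------------
# run configuration & logging
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Printed constants of the diagnostic workflow.

    Defaults are the published selection rules: top 5,000 most-variable genes,
    a log2 fold-change screen at |log2 FC| >= 1 (FC 2), a handling-stress SD
    cut of 0.32, an individual-effect coefficient cut of 0.5, and an FDR cut
    q <= 0.05.
    """

    top_n_variance: int = 5000
    fc_threshold_log2: float = 1.0
    handling_sd_threshold: float = 0.32
    individual_coef_threshold: float = 0.5
    individual_coef_inclusive: bool = False   # strict ">" by default
    q_threshold: float = 0.05
    n_permutations: int = 300
    rng_seed: int = 0
    variance_tail_k_early: Optional[int] = None   # None -> use quantile
    variance_tail_k_late: Optional[int] = None
    variance_tail_quantile: float = 0.8
    coherence_within_threshold: float = 0.8
    coherence_between_threshold: float = 0.3
    late_b1_includes_t0: bool = True  # both t0 and t7.5 relabel to b1

    def __post_init__(self) -> None:
        for name in ("top_n_variance", "fc_threshold_log2", "handling_sd_threshold",
                     "individual_coef_threshold", "q_threshold", "n_permutations"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 < self.variance_tail_quantile <= 1:
            raise ConfigError("variance_tail_quantile must be in (0, 1]")


def load_config(path: str | Path) -> PipelineConfig:
    with Path(path).open("r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: expected a mapping of config keys")
    unknown = set(data) - {f.name for f in PipelineConfig.__dataclass_fields__.values()}
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    return PipelineConfig(**data)


def setup_logging(verbose: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("confounderscan")
    root.handlers[:] = [handler]
    root.setLevel(logging.DEBUG if verbose else logging.INFO)
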