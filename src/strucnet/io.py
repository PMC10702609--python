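"""File formats, pipeline configuration and run manifests.

Matrices travel as labeled TSV (region abbreviations as header row and
column); cohorts as one matrix file per subject plus a CSV manifest
(subject_id, group, file); results as tidy CSV.  Numeric output uses 17
significant digits so every file round-trips to 1e-12.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import RegionAtlas
from .connectome import ConnectomeConfig, SubjectConnectome
from .graph_metrics import NullModelConfig
from .simulate import CohortConfig
from .stats import StatsConfig

__all__ = [
    "MatrixFormatError",
    "read_matrix_table",
    "write_matrix_table",
    "write_cohort",
    "read_cohort",
    "PipelineConfig",
    "RunManifest",
]

FLOAT_FORMAT = "%.17g"
SYMMETRY_TOLERANCE = 1e-9


class MatrixFormatError(ValueError):
    """Raised when a matrix file violates the labeled-TSV contract."""


def read_matrix_table(path: str | Path, atlas: RegionAtlas | None = None) -> pd.DataFrame:
    """Read a labeled symmetric matrix from TSV.

    Row and column label sets must match; asymmetries within 1e-9 are
    silently symmetrized, larger ones symmetrized with a warning.  With an
    atlas, labels must be known abbreviations.
    """
    # keep_default_na: "NA" is a region abbreviation, not a missing value
    df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False,
                     na_values=[""])
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise MatrixFormatError(f"{path}: row and column labels differ")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise MatrixFormatError(f"{path}: non-numeric cell ({exc})") from None
    if not np.isfinite(values).all():
        raise MatrixFormatError(f"{path}: non-finite cell")
    if atlas is not None:
        unknown = [l for l in df.index if l not in atlas]
        if unknown:
            raise MatrixFormatError(f"{path}: labels not in atlas: {unknown[:5]}")
    asym = np.abs(values - values.T).max() if values.size else 0.0
    if asym > SYMMETRY_TOLERANCE:
        warnings.warn(f"{path}: matrix asymmetric by {asym:.3g}; symmetrizing",
                      stacklevel=2)
    sym = (values + values.T) / 2.0
    return pd.DataFrame(sym, index=df.index, columns=df.columns)


def write_matrix_table(matrix, path: str | Path,
                       labels: Sequence[str] | None = None) -> Path:
    """Write a labeled matrix (DataFrame, or array + labels) as TSV."""
    if isinstance(matrix, pd.DataFrame):
        df = matrix
    else:
        arr = np.asarray(getattr(matrix, "weights", matrix))
        if labels is None:
            labels = getattr(matrix, "labels", None)
        if labels is None:
            raise ValueError("labels required for a bare array")
        df = pd.DataFrame(arr, index=list(labels), columns=list(labels))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)
    return path


def write_matrix_market(matrix, path: str | Path,
                        labels: Sequence[str] | None = None) -> Path:
    """Optional sparse (MatrixMarket triplet) export of a labeled matrix;
    labels go to a side-car ``.labels`` file, one per line."""
    from scipy import io as spio
    from scipy import sparse

    arr = np.asarray(getattr(matrix, "weights", matrix))
    if labels is None:
        labels = getattr(matrix, "labels", None)
    if isinstance(matrix, pd.DataFrame):
        arr, labels = matrix.to_numpy(), list(matrix.index)
    if labels is None:
        raise ValueError("labels required for a bare array")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(path, sparse.coo_matrix(arr))
    path.with_suffix(path.suffix + ".labels").write_text(
        "\n".join(labels) + "\n")
    return path


def write_cohort(subjects: Sequence[SubjectConnectome], outdir: str | Path,
                 atlas: RegionAtlas) -> Path:
    """Write one matrix TSV per subject plus a cohort manifest CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = list(atlas.abbreviations)
    records = []
    for s in subjects:
        fname = f"{s.subject_id}.tsv"
        write_matrix_table(pd.DataFrame(s.counts, index=labels, columns=labels),
                           outdir / fname)
        records.append({"subject_id": s.subject_id, "group": s.group, "file": fname})
    manifest = outdir / "cohort.csv"
    pd.DataFrame(records).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest: str | Path, atlas: RegionAtlas) -> list[SubjectConnectome]:
    """Read a cohort written by :func:`write_cohort`."""
    manifest = Path(manifest)
    table = pd.read_csv(manifest)
    subjects = []
    for rec in table.to_dict("records"):
        df = read_matrix_table(manifest.parent / rec["file"], atlas=atlas)
        counts = df.to_numpy()
        rounded = np.rint(counts)
        if np.abs(counts - rounded).max() > 1e-6:
            raise MatrixFormatError(f"{rec['file']}: counts are not integers")
        subjects.append(SubjectConnectome(
            subject_id=str(rec["subject_id"]), group=str(rec["group"]),
            counts=rounded.astype(np.int64)))
    return subjects


# -- configuration -----------------------------------------------------------

def _plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _plain(v) for k, v in dataclasses.asdict(obj).items()
                if k != "atlas"}
    if isinstance(obj, tuple):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


@dataclass(frozen=True)
class PipelineConfig:
    """Composite configuration for a pipeline run (one YAML file)."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    connectome: ConnectomeConfig = field(default_factory=ConnectomeConfig)
    null_model: NullModelConfig = field(default_factory=NullModelConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def to_dict(self) -> dict:
        return {"cohort": _plain(self.cohort),
                "connectome": _plain(self.connectome),
                "null_model": _plain(self.null_model),
                "stats": _plain(self.stats)}

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cohort = dict(raw.get("cohort", {}))
        for key in ("effect_edges", "backbone_edges"):
            if key in cohort:
                cohort[key] = tuple(tuple(e) for e in cohort[key])
        return cls(
            cohort=CohortConfig(**cohort),
            connectome=ConnectomeConfig(**raw.get("connectome", {})),
            null_model=NullModelConfig(**raw.get("null_model", {})),
            stats=StatsConfig(**raw.get("stats", {})),
        )

    def with_seed(self, seed: int) -> "PipelineConfig":
        return dataclasses.replace(
            self,
            cohort=dataclasses.replace(self.cohort, rng_seed=seed),
            null_model=dataclasses.replace(self.null_model, rng_seed=seed),
        )


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline stage."""

    stage: str
    seed: int
    config: dict
    outputs: list[str] = field(default_factory=list)
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat())

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        return path
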