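"""In-memory containers for the two measurement types and their TSV forms.

Both containers wrap a pandas DataFrame with features in rows and samples in
columns. Microbiome profiles are compositional (columns sum to one); metabolite
matrices are unclosed positive intensities in which missingness is an explicit
state (NaN in memory, ``NA`` on disk), never zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ProfileLevel", "AbundanceTable", "MetaboliteMatrix"]

CLOSURE_TOL = 1e-9

#: Profile levels produced by taxonomic/functional profiling upstream.
ProfileLevel = ("PHYLUM", "SPECIES", "GENE", "PATHWAY", "RESISTANCE_GENE")


@dataclass
class AbundanceTable:
    """Relative-abundance matrix (features x samples) tagged with its level.

    ``closed`` records whether columns are on the simplex; a square-root
    transform deliberately breaks closure and flips this flag.
    """

    data: pd.DataFrame
    level: str = "SPECIES"
    closed: bool = True

    def __post_init__(self):
        if self.level not in ProfileLevel:
            raise ValueError(f"unknown profile level {self.level!r}")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("relative abundances must be >= 0")
        if self.closed:
            sums = self.data.sum(axis=0).to_numpy()
            ok = np.isclose(sums, 1.0, atol=1e-6) | (sums == 0)
            if not ok.all():
                raise ValueError("columns of a closed table must sum to 1")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        return AbundanceTable(self.data[list(sample_ids)], level=self.level, closed=self.closed)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "feature_id", out.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, level: str = "SPECIES", closed: bool = True) -> "AbundanceTable":
        df = pd.read_csv(path, sep="\t").set_index("feature_id")
        df.index.name = None
        return cls(df, level=level, closed=closed)


@dataclass
class MetaboliteMatrix:
    """Metabolite intensities with explicit missingness and QC injections.

    ``qc_columns`` flags pooled-QC injection columns (replicate measurements of
    a pool combining aliquots of all study samples). ``annotations`` carries
    pass-through feature metadata: name, class label and adduct group id.
    """

    data: pd.DataFrame
    qc_columns: list[str] = field(default_factory=list)
    annotations: pd.DataFrame | None = None

    def __post_init__(self):
        unknown = set(self.qc_columns) - set(self.data.columns)
        if unknown:
            raise ValueError(f"qc_columns not in matrix: {sorted(unknown)}")
        vals = self.data.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) <= 0:
            raise ValueError("present intensities must be > 0 (missing is NaN, never 0)")
        if self.annotations is not None:
            extra = set(self.annotations.index) ^ set(self.data.index)
            if extra:
                warnings.warn(f"annotations/matrix feature mismatch: {len(extra)} ids")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def study_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in set(self.qc_columns)]

    @property
    def qc_data(self) -> pd.DataFrame:
        return self.data[self.qc_columns]

    def subset_features(self, feature_ids) -> "MetaboliteMatrix":
        keep = [f for f in self.feature_ids if f in set(feature_ids)]
        ann = self.annotations.loc[keep] if self.annotations is not None else None
        return MetaboliteMatrix(self.data.loc[keep], qc_columns=list(self.qc_columns), annotations=ann)

    def to_tsv(self, path: str | Path, annotations_path: str | Path | None = None) -> None:
        out = self.data.copy()
        out.columns = [f"QC_{c}" if c in set(self.qc_columns) else c for c in out.columns]
        out.insert(0, "feature_id", out.index)
        out.to_csv(path, sep="\t", index=False, na_rep="NA")
        if annotations_path is not None and self.annotations is not None:
            ann = self.annotations.copy()
            ann.insert(0, "feature_id", ann.index)
            ann.to_csv(annotations_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, annotations_path: str | Path | None = None) -> "MetaboliteMatrix":
        df = pd.read_csv(path, sep="\t", na_values=["NA"]).set_index("feature_id")
        df.index.name = None
        qc = [c for c in df.columns if c.startswith("QC_")]
        df = df.rename(columns={c: c[3:] for c in qc})
        ann = None
        if annotations_path is not None:
            ann = pd.read_csv(annotations_path, sep="\t").set_index("feature_id")
            ann.index.name = None
        return cls(df, qc_columns=[c[3:] for c in qc], annotations=ann)
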