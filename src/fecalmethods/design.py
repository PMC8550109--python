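"""Crossed subject x method x timepoint study design and comparison pairings.

The design under evaluation: each subject self-collects one stool specimen
that is split into aliquots, one per collection method and storage timepoint.
A gold-standard aliquot (GS) is frozen at -80C immediately with no
preservative; every other method yields one aliquot frozen on day 0 and one
kept at ambient temperature for four days before freezing (day 4), emulating
field transport. Three paired comparisons per non-reference method define the
estimands assessed downstream:

* STABILITY    — (method, D4) vs (method, D0): temporal drift within a method.
* CONCORDANCE  — (method, D0) vs (GS, D0): bias introduced by the preservative.
* RELIABILITY  — (method, D4) vs (GS, D0): the combined field-use error.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "Timepoint",
    "Mode",
    "MethodSpec",
    "ComparisonMode",
    "SampleManifest",
    "DesignError",
    "GS",
    "default_methods",
    "generate_manifest",
    "select_pairs",
    "read_manifest",
    "write_manifest",
]

GS = "GS"


class DesignError(ValueError):
    """Raised when a study design is internally inconsistent."""


class Timepoint(str, enum.Enum):
    D0 = "D0"
    D4 = "D4"


class Mode(str, enum.Enum):
    STABILITY = "STABILITY"
    CONCORDANCE = "CONCORDANCE"
    RELIABILITY = "RELIABILITY"


@dataclass(frozen=True)
class MethodSpec:
    """One collection method and the storage timepoints it contributes.

    The gold standard is frozen immediately only (``timepoints == {"D0"}``).
    FOBT cards yield too little material for metabolomics, hence
    ``supports_metabolomics=False`` for that method in the default design.
    """

    method_id: str
    timepoints: frozenset = field(default_factory=lambda: frozenset({"D0", "D4"}))
    supports_metabolomics: bool = True

    def __post_init__(self):
        tps = frozenset(str(t) for t in self.timepoints)
        object.__setattr__(self, "timepoints", tps)
        bad = tps - {"D0", "D4"}
        if bad:
            raise DesignError(f"unknown timepoints {sorted(bad)} for {self.method_id}")
        if not tps:
            raise DesignError(f"method {self.method_id} has no timepoints")
        if self.method_id == GS and tps != {"D0"}:
            raise DesignError("GS is frozen immediately: timepoints must be {D0}")


def default_methods() -> list[MethodSpec]:
    """The six-method design: GS plus five ambient-storage methods."""
    return [
        MethodSpec(GS, frozenset({"D0"})),
        MethodSpec("ETOH95"),
        MethodSpec("RNALATER"),
        MethodSpec("MICROLUTION"),
        MethodSpec("OMNIGENE"),
        MethodSpec("FOBT", supports_metabolomics=False),
    ]


@dataclass(frozen=True)
class ComparisonMode:
    """A comparison estimand for one evaluated (non-GS) method."""

    mode: Mode
    method_id: str

    def __post_init__(self):
        object.__setattr__(self, "mode", Mode(self.mode))
        if self.method_id == GS:
            raise DesignError("GS is the reference and cannot be the evaluated method")

    @property
    def evaluated(self) -> tuple[str, str]:
        """(method, timepoint) of the evaluated member of each pair."""
        if self.mode is Mode.STABILITY or self.mode is Mode.RELIABILITY:
            return (self.method_id, "D4")
        return (self.method_id, "D0")

    @property
    def reference(self) -> tuple[str, str]:
        """(method, timepoint) of the reference member of each pair."""
        if self.mode is Mode.STABILITY:
            return (self.method_id, "D0")
        return (GS, "D0")


@dataclass
class SampleManifest:
    """The sample sheet: one record per (subject, method, timepoint).

    ``records`` columns: sample_id, subject_id, method, timepoint, alias
    (alias is the within-subject 1..k numbering of the classical design sheet).
    """

    records: pd.DataFrame
    methods: dict[str, MethodSpec] = field(default_factory=dict)

    def __post_init__(self):
        req = ["sample_id", "subject_id", "method", "timepoint"]
        missing = [c for c in req if c not in self.records.columns]
        if missing:
            raise DesignError(f"manifest missing columns {missing}")
        trip = self.records[["subject_id", "method", "timepoint"]]
        if trip.duplicated().any():
            raise DesignError("duplicate (subject, method, timepoint) triples")
        if self.records["sample_id"].duplicated().any():
            raise DesignError("duplicate sample_id")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.records["sample_id"])

    @property
    def subjects(self) -> list[str]:
        return sorted(self.records["subject_id"].unique())

    def __len__(self) -> int:
        return len(self.records)

    def lookup(self, subject_id: str, method: str, timepoint: str) -> str | None:
        r = self.records
        hit = r[
            (r["subject_id"] == subject_id)
            & (r["method"] == method)
            & (r["timepoint"] == timepoint)
        ]
        return None if hit.empty else str(hit["sample_id"].iloc[0])

    def metadata_for(self, sample_ids) -> pd.DataFrame:
        """Per-sample factor labels (subject, method, timepoint), sample-indexed."""
        meta = self.records.set_index("sample_id").loc[list(sample_ids)]
        return meta[["subject_id", "method", "timepoint"]]


def generate_manifest(n_subjects: int, methods: list[MethodSpec] | None = None) -> SampleManifest:
    """Enumerate the full crossed design, deterministically sorted.

    Sample ids follow ``S{subject:02d}_{method}_{timepoint}``; the alias column
    numbers samples 1..k within each subject (GS first, then the methods in the
    order given, D0 before D4), matching conventional design-sheet numbering.
    """
    if methods is None:
        methods = default_methods()
    if n_subjects < 1:
        raise DesignError("n_subjects must be >= 1")
    if not methods:
        raise DesignError("methods must be non-empty")
    ids = [m.method_id for m in methods]
    if len(set(ids)) != len(ids):
        raise DesignError("duplicate method ids")
    if sum(m.method_id == GS for m in methods) != 1:
        raise DesignError("exactly one GS method is required")

    ordered = sorted(methods, key=lambda m: (m.method_id != GS, ids.index(m.method_id)))
    rows = []
    for s in range(1, n_subjects + 1):
        subject = f"S{s:02d}"
        alias = 0
        for m in ordered:
            for tp in sorted(m.timepoints):
                alias += 1
                rows.append(
                    {
                        "sample_id": f"{subject}_{m.method_id}_{tp}",
                        "subject_id": subject,
                        "method": m.method_id,
                        "timepoint": tp,
                        "alias": alias,
                    }
                )
    records = pd.DataFrame(rows)
    return SampleManifest(records=records, methods={m.method_id: m for m in methods})


def select_pairs(manifest: SampleManifest, comparison: ComparisonMode) -> pd.DataFrame:
    """One (evaluated, reference) sample pair per subject for a comparison.

    Subjects lacking either member are dropped with a warning; the evaluated
    member is always first. Returns columns subject_id, evaluated, reference.
    """
    ev_method, ev_tp = comparison.evaluated
    ref_method, ref_tp = comparison.reference
    rows, dropped = [], []
    for subject in manifest.subjects:
        a = manifest.lookup(subject, ev_method, ev_tp)
        b = manifest.lookup(subject, ref_method, ref_tp)
        if a is None or b is None:
            dropped.append(subject)
            continue
        rows.append({"subject_id": subject, "evaluated": a, "reference": b})
    if dropped:
        warnings.warn(
            f"{comparison.mode.value}/{comparison.method_id}: dropped subjects "
            f"missing a pair member: {dropped}",
            stacklevel=2,
        )
    return pd.DataFrame(rows, columns=["subject_id", "evaluated", "reference"])


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    cols = ["sample_id", "subject_id", "method", "timepoint"]
    if "alias" in manifest.records.columns:
        cols = cols + ["alias"]
    manifest.records[cols].to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> SampleManifest:
    records = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    return SampleManifest(records=records)
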