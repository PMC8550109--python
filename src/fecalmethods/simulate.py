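"""Synthetic microbiome and metabolome profiles with the study's variance structure.

The generator emulates a crossed subject x method x timepoint collection-method
study: a dominant between-subject effect, smaller preservative (method) and
ambient-storage (day-4 drift) effects, residual measurement noise, and — for
metabolites — left-censoring at a detection limit plus pooled-QC injections.

Per feature f, sample (subject s, method m, timepoint tp) the log-scale model is

    y = mu_f + b(s,f) + m(s,m,f) + 1[tp=D4] * ( delta_t_m * u(m,f) + sigma_t_m * z(s,m,f) ) + eps

with b ~ N(0, sigma_b^2), m(s,m,f) ~ N(0, sigma_m^2), u(m,f) ~ N(0,1) a fixed
per-feature systematic drift direction scaled by delta_t, z ~ N(0,1), and
eps ~ N(0, sigma_e^2). The gold standard carries no method or drift terms.
Microbiome tables are exponentiated and column-normalized (compositional
closure); metabolite intensities stay unclosed and are censored below ``lod``.

Because the consistency ICC removes any effect shared by all subjects in one
measurement column, the systematic drift ``delta_t * u(m,f)`` does not enter
the per-feature ICC of unclosed intensities; it degrades microbiome ICCs only
through compositional closure. The closed-form target implemented by
:func:`expected_icc` is therefore exact for unclosed, uncensored features:

    ICC = sigma_s^2 / (sigma_s^2 + sigma_w^2),   sigma_w^2 = sigma_e^2 + extra/2

where extra is the subject-varying part of the pair-difference variance beyond
residuals — sigma_t^2 (stability), sigma_m^2 (concordance) or
sigma_m^2 + sigma_t^2 (reliability) — and sigma_s^2 is the shared
between-subject signal: sigma_b^2 + sigma_m^2 for stability (both members of a
stability pair carry the same subject-level preservative effect), sigma_b^2
for the two GS-referenced modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import GS, ComparisonMode, Mode, SampleManifest
from .tables import AbundanceTable, MetaboliteMatrix

__all__ = [
    "SimulationParams",
    "default_microbiome_params",
    "default_metabolome_params",
    "simulate_microbiome",
    "simulate_metabolome",
    "expected_icc",
]

#: Named metabolite class proportions at the >=80% detectability level in a
#: typical untargeted fecal profile; the remainder is unnamed.
_CLASS_WEIGHTS = {
    "lipid": 0.176,
    "peptide": 0.039,
    "amino_acid": 0.027,
    "nucleotide": 0.009,
    "cofactors_vitamins": 0.007,
    "carbohydrate": 0.005,
    "xenobiotics": 0.002,
    "energy": 0.001,
}


@dataclass(frozen=True)
class SimulationParams:
    """Variance components and censoring/QC settings for one simulated level.

    SDs are on the natural-log scale. ``sigma_m``, ``delta_t`` and ``sigma_t``
    accept either a scalar (all methods) or a per-method mapping; the ethanol
    defaults are elevated to encode the qualitative finding that 95% ethanol
    preserves microbiome profiles least stably at ambient temperature.
    """

    n_features: int = 200
    mu_mean: float = 0.0
    mu_sd: float = 2.0
    sigma_b: float = 1.0
    sigma_m: float | dict = 0.3
    delta_t: float | dict = field(default_factory=lambda: {"ETOH95": 0.8, "default": 0.2})
    sigma_t: float | dict = field(default_factory=lambda: {"ETOH95": 0.5, "default": 0.2})
    sigma_e: float = 0.2
    lod: float = 0.0
    n_qc: int = 8
    sigma_qc: float = 0.05
    adduct_dup_frac: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_features < 2:
            raise ValueError("n_features must be >= 2 (composition undefined otherwise)")
        for name in ("sigma_b", "sigma_e", "mu_sd", "sigma_qc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("sigma_m", "sigma_t"):
            v = getattr(self, name)
            vals = v.values() if isinstance(v, dict) else [v]
            if any(x < 0 for x in vals):
                raise ValueError(f"{name} must be >= 0")
        if self.lod < 0:
            raise ValueError("lod must be >= 0 on the intensity scale")
        if self.n_qc < 0:
            raise ValueError("n_qc must be >= 0")

    def per_method(self, name: str, method: str) -> float:
        v = getattr(self, name)
        if isinstance(v, dict):
            return float(v.get(method, v.get("default", 0.0)))
        return float(v)

    def with_(self, **kwargs) -> "SimulationParams":
        return replace(self, **kwargs)


def default_microbiome_params(seed: int = 0, n_features: int = 200) -> SimulationParams:
    return SimulationParams(n_features=n_features, seed=seed)


def default_metabolome_params(seed: int = 0, n_features: int = 1998) -> SimulationParams:
    """Defaults sized to a ~2,000-feature untargeted fecal metabolome.

    Baseline intensities are log-normal around 1e4 counts; the detection limit
    sits in the lower tail so that per-method detectability spans the <50%,
    >=80% and 100% bands, and OMNIgene's larger negative-drift spread yields
    the lowest day-4 detectability, mirroring the study's qualitative ranking.
    """
    return SimulationParams(
        n_features=n_features,
        mu_mean=float(np.log(1e4)),
        mu_sd=1.5,
        sigma_b=1.0,
        sigma_m={"ETOH95": 0.2, "OMNIGENE": 0.6, "default": 0.35},
        delta_t={"ETOH95": 0.15, "OMNIGENE": 0.8, "RNALATER": 0.6, "default": 0.3},
        sigma_t={"ETOH95": 0.25, "OMNIGENE": 0.7, "RNALATER": 0.55, "default": 0.35},
        sigma_e=0.25,
        lod=450.0,
        n_qc=8,
        sigma_qc=0.05,
        adduct_dup_frac=0.1,
        seed=seed,
    )


def _log_matrix(
    manifest: SampleManifest, params: SimulationParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw the shared linear model on the log scale (features x samples).

    Draw shapes depend only on the design and n_features, never on parameter
    values, so matched seeds stay matched when a variance component is dialed.
    """
    records = manifest.records
    subjects = sorted(records["subject_id"].unique())
    methods = sorted(records["method"].unique())
    s_index = {s: i for i, s in enumerate(subjects)}
    nf, ns = params.n_features, len(subjects)

    mu = params.mu_mean + params.mu_sd * rng.standard_normal(nf)
    b = params.sigma_b * rng.standard_normal((ns, nf))
    u_drift = {m: rng.standard_normal(nf) for m in methods if m != GS}
    m_eff = {m: rng.standard_normal((ns, nf)) for m in methods if m != GS}
    z_drift = {m: rng.standard_normal((ns, nf)) for m in methods if m != GS}
    eps = params.sigma_e * rng.standard_normal((nf, len(records)))

    cols = {}
    for j, rec in enumerate(records.itertuples(index=False)):
        si = s_index[rec.subject_id]
        y = mu + b[si] + eps[:, j]
        if rec.method != GS:
            y = y + params.per_method("sigma_m", rec.method) * m_eff[rec.method][si]
            if rec.timepoint == "D4":
                y = y + (
                    params.per_method("delta_t", rec.method) * u_drift[rec.method]
                    + params.per_method("sigma_t", rec.method) * z_drift[rec.method][si]
                )
        cols[rec.sample_id] = y
    feature_ids = [f"f{i:05d}" for i in range(nf)]
    return pd.DataFrame(cols, index=feature_ids)


def simulate_microbiome(
    manifest: SampleManifest, params: SimulationParams, level: str = "SPECIES"
) -> AbundanceTable:
    """Compositional relative-abundance table: exp of the log model, closed to 1."""
    rng = np.random.default_rng(params.seed)
    logy = _log_matrix(manifest, params, rng)
    x = np.exp(logy - logy.max(axis=0))  # guard overflow; closure absorbs the shift
    rel = x / x.sum(axis=0)
    rel.index = [f"{level.lower()}_{i:05d}" for i in range(params.n_features)]
    return AbundanceTable(rel, level=level, closed=True)


def simulate_metabolome(manifest: SampleManifest, params: SimulationParams) -> MetaboliteMatrix:
    """Unclosed intensity matrix with LOD censoring, QC injections and adducts.

    Methods flagged ``supports_metabolomics=False`` in the manifest (FOBT in
    the default design) contribute no columns. QC columns are noisy replicates
    of the per-feature pooled geometric mean, censored at the same LOD.
    """
    rng = np.random.default_rng(params.seed)
    no_metab = {
        mid for mid, spec in manifest.methods.items() if not spec.supports_metabolomics
    } or {"FOBT"}
    keep = ~manifest.records["method"].isin(no_metab)
    sub = SampleManifest(records=manifest.records[keep].reset_index(drop=True), methods=manifest.methods)

    logy = _log_matrix(sub, params, rng)
    logy.index = [f"met_{i:05d}" for i in range(params.n_features)]

    # Adduct duplicates: a few metabolites appear as a second, noisier ion.
    n_dup = int(params.adduct_dup_frac * params.n_features)
    dup_ids = list(logy.index[:n_dup])
    adduct_group = {fid: fid for fid in logy.index}
    if n_dup:
        extra = logy.loc[dup_ids] + 2.0 * params.sigma_qc * rng.standard_normal((n_dup, logy.shape[1]))
        extra.index = [f"{fid}_add2" for fid in dup_ids]
        for fid in dup_ids:
            adduct_group[f"{fid}_add2"] = fid
        logy = pd.concat([logy, extra])

    intensities = np.exp(logy)

    pooled = logy.mean(axis=1)
    # QC injections get doubled instrument noise on the duplicated adduct ions
    # so the lowest-RSD ion per group is the primary one.
    noise_scale = np.array([2.0 if f.endswith("_add2") else 1.0 for f in logy.index])
    qc_cols = {}
    for q in range(params.n_qc):
        noise = params.sigma_qc * noise_scale * rng.standard_normal(len(pooled))
        qc_cols[f"QC{q + 1:02d}"] = np.exp(pooled + noise)
    qc = pd.DataFrame(qc_cols, index=logy.index)
    full = pd.concat([intensities, qc], axis=1)

    censored = full.mask(full < params.lod)

    class_ids = list(_CLASS_WEIGHTS) + ["unnamed"]
    probs = list(_CLASS_WEIGHTS.values())
    probs.append(1.0 - sum(probs))
    base_classes = rng.choice(class_ids, size=params.n_features, p=probs)
    class_by_base = dict(zip([f"met_{i:05d}" for i in range(params.n_features)], base_classes))
    ann = pd.DataFrame(
        {
            "name": [adduct_group[f] for f in logy.index],
            "class": [class_by_base[adduct_group[f]] for f in logy.index],
            "adduct_group": [adduct_group[f] for f in logy.index],
        },
        index=logy.index,
    )
    return MetaboliteMatrix(censored, qc_columns=list(qc_cols), annotations=ann)


def expected_icc(params: SimulationParams, comparison: ComparisonMode) -> float:
    """Closed-form consistency-ICC target for unclosed, uncensored features.

    sigma_w^2 is half the subject-varying pair-difference variance implied by
    the generative model for the given comparison (see module docstring).
    Systematic drift delta_t is a column effect and drops out; in a stability
    pair the subject-level method effect is shared by both members and counts
    as between-subject signal.
    """
    sm = params.per_method("sigma_m", comparison.method_id)
    st = params.per_method("sigma_t", comparison.method_id)
    extra = {
        Mode.STABILITY: st**2,
        Mode.CONCORDANCE: sm**2,
        Mode.RELIABILITY: sm**2 + st**2,
    }[comparison.mode]
    shared = sm**2 if comparison.mode is Mode.STABILITY else 0.0
    sigma_w2 = params.sigma_e**2 + extra / 2.0
    sigma_s2 = params.sigma_b**2 + shared
    if sigma_s2 == 0:
        return 0.0
    if sigma_w2 == 0:
        return 1.0
    return sigma_s2 / (sigma_s2 + sigma_w2)
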