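"""Synthetic two-group ocular cohort generator with a ground-truth record.

Emulates the data layout of a case-control glaucoma study: clinical
covariates and OCT/OCT-A structural and perfusion measures with per-group
location/scale, a multiplex analyte panel measured in two compartments
(plasma and aqueous humor) with log-normal levels, planted group effects
(log2 fold changes), analyte-to-perfusion couplings on standardized scales,
left-censoring at a detection limit, heavy-tail outlier contamination and
missingness.  Every corrupted cell is recorded in a :class:`GroundTruth` so
downstream screening stages can be tested for recovery without patient data.

Corruption order is couplings -> censoring -> outliers -> missingness,
mimicking a measurement-then-recording process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import (CONTROL, GLAUCOMA, GROUP_COLUMN, CohortTable, VariableMeta)

LN2 = math.log(2.0)


# --------------------------------------------------------------------------
# configuration dataclasses
# --------------------------------------------------------------------------

@dataclass
class AnalyteSpec:
    """One analyte in one compartment, log-normally distributed.

    ``log_mean``/``log_sd`` parameterize the natural-log concentration in the
    control group; ``log2_fc`` is the planted glaucoma-vs-control group effect
    in log2 units; ``lod`` the assay detection limit on the concentration
    scale (values below it are recorded as 0 / not detected).
    """

    name: str
    compartment: str  # "plasma" | "AqH"
    log_mean: float = 4.0
    log_sd: float = 0.5
    lod: float = 0.0
    log2_fc: float = 0.0

    @property
    def column(self) -> str:
        return f"{self.name}_{self.compartment}"


@dataclass
class VariableSpec:
    """A clinical or OCT/OCT-A variable with per-group parameters.

    Continuous variables draw from a normal with per-group ``mean``/``sd``;
    nominal and dichotomous variables draw categories from per-group
    probability tables.
    """

    name: str
    scale: str = "continuous"  # continuous | dichotomous | nominal
    role: str = "independent"  # independent | dependent-candidate
    mean: Mapping[str, float] | None = None    # group -> mean
    sd: Mapping[str, float] | None = None      # group -> sd
    categories: Mapping[str, Mapping[str, float]] | None = None  # group -> {level: p}


@dataclass
class CouplingSpec:
    """Additive analyte -> target coupling on standardized scales.

    The target's standardized residual is ``sum_j c_j z_j + sqrt(1-sum c^2) eps``
    over all couplings j into that target, with ``z_j`` the standardized
    log-level of the source analyte; ``coef`` is one ``c_j``.  With the
    coupled coefficients summing to unit squared norm the target carries no
    independent noise.
    """

    analyte: str          # column name, e.g. "APN_AqH"
    target: str           # variable name, e.g. "VD_PeriONH_Average"
    coef: float = 0.3


@dataclass
class SyntheticConfig:
    n_control: int = 30
    n_glaucoma: int = 87
    analytes: Sequence[AnalyteSpec] = field(default_factory=list)
    variables: Sequence[VariableSpec] = field(default_factory=list)
    couplings: Sequence[CouplingSpec] = field(default_factory=list)
    outlier_rate: float = 0.0
    outlier_scale: float = 10.0
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_control < 2:
            raise ValueError("n_control must be >= 2")
        if self.n_glaucoma < 2:
            raise ValueError("n_glaucoma must be >= 2")
        for rate_name in ("outlier_rate", "missing_rate"):
            r = getattr(self, rate_name)
            if not (0.0 <= r < 1.0):
                raise ValueError(f"{rate_name} must be in [0, 1)")
        if self.outlier_scale <= 1.0:
            raise ValueError("outlier_scale must be > 1")
        for a in self.analytes:
            if a.log_sd <= 0:
                raise ValueError(f"log_sd must be > 0 for analyte {a.name}")
            if a.lod < 0:
                raise ValueError(f"lod must be >= 0 for analyte {a.name}")
        for v in self.variables:
            if v.scale == "continuous" and v.sd is not None:
                for g, s in v.sd.items():
                    if s < 0:
                        raise ValueError(f"sd must be >= 0 for variable {v.name}")
        targets: dict[str, float] = {}
        for c in self.couplings:
            targets[c.target] = targets.get(c.target, 0.0) + c.coef ** 2
        for t, ssq in targets.items():
            if ssq > 1.0 + 1e-12:
                raise ValueError(f"coupling coefficients into {t} exceed unit squared norm")


@dataclass
class GroundTruth:
    """Planted effects, couplings and corruption masks for recovery tests."""

    analyte_log2_fc: dict[str, float]
    coupling_coefs: dict[tuple[str, str], float]
    outlier_mask: pd.DataFrame
    missing_mask: pd.DataFrame
    censor_mask: pd.DataFrame
    seed: int


# --------------------------------------------------------------------------
# primitives
# --------------------------------------------------------------------------

def apply_lod_censoring(values: np.ndarray, lod: float) -> tuple[np.ndarray, np.ndarray]:
    """Left-censor a concentration vector at a detection limit.

    Values strictly below ``lod`` become 0 with the detected flag cleared;
    values at or above it pass through with the flag set.  Missing (NaN)
    entries keep NaN and a cleared flag.
    """
    if lod < 0:
        raise ValueError("lod must be >= 0")
    values = np.asarray(values, dtype=float)
    detected = ~np.isnan(values) & (values >= lod)
    censored = np.where(np.isnan(values), np.nan, np.where(detected, values, 0.0))
    return censored, detected


# --------------------------------------------------------------------------
# generator
# --------------------------------------------------------------------------

def generate_cohort(config: SyntheticConfig) -> tuple[CohortTable, GroundTruth]:
    """Draw one cohort and its ground truth, fully reproducible from the seed."""
    config.validate()
    # independent child streams per stage so that e.g. raising missing_rate
    # does not perturb the analyte draws
    ss = np.random.SeedSequence(config.seed)
    rng_clin, rng_analyte, rng_censor, rng_outlier, rng_missing = (
        np.random.default_rng(s) for s in ss.spawn(5))

    n = config.n_control + config.n_glaucoma
    groups = np.array([CONTROL] * config.n_control + [GLAUCOMA] * config.n_glaucoma)
    index = pd.Index([f"S{i + 1:04d}" for i in range(n)], name="sample_id")
    data = pd.DataFrame({GROUP_COLUMN: groups}, index=index)
    meta: dict[str, VariableMeta] = {}

    # clinical / OCT variables
    for spec in config.variables:
        if spec.scale == "continuous":
            vals = np.empty(n)
            for g in (CONTROL, GLAUCOMA):
                m = groups == g
                vals[m] = rng_clin.normal(spec.mean[g], spec.sd[g], m.sum())
            data[spec.name] = vals
        else:
            col = np.empty(n, dtype=object)
            for g in (CONTROL, GLAUCOMA):
                m = groups == g
                levels = list(spec.categories[g])
                probs = np.array([spec.categories[g][l] for l in levels], dtype=float)
                probs = probs / probs.sum()
                col[m] = rng_clin.choice(levels, size=m.sum(), p=probs)
            # all-numeric category labels become a numeric column (round-trips cleanly)
            try:
                col = col.astype(float)
            except (TypeError, ValueError):
                pass
            data[spec.name] = col
        meta[spec.name] = VariableMeta(role=spec.role, scale=spec.scale)

    # analytes: log-normal with planted group shift (log2 FC -> natural log)
    log_levels: dict[str, np.ndarray] = {}
    fc: dict[str, float] = {}
    for a in config.analytes:
        mu = np.where(groups == GLAUCOMA, a.log_mean + a.log2_fc * LN2, a.log_mean)
        log_levels[a.column] = rng_analyte.normal(mu, a.log_sd)
        data[a.column] = np.exp(log_levels[a.column])
        meta[a.column] = VariableMeta(role="independent", scale="continuous",
                                      compartment=a.compartment, lod=a.lod)
        fc[a.column] = a.log2_fc

    # couplings: rewrite each coupled target's standardized residual
    by_target: dict[str, list[CouplingSpec]] = {}
    for c in config.couplings:
        if c.analyte not in log_levels:
            raise ValueError(f"coupling source {c.analyte!r} is not a configured analyte")
        by_target.setdefault(c.target, []).append(c)
    coup: dict[tuple[str, str], float] = {}
    var_by_name = {v.name: v for v in config.variables}
    for target, specs in by_target.items():
        if target not in var_by_name or var_by_name[target].scale != "continuous":
            raise ValueError(f"coupling target {target!r} is not a continuous variable")
        vspec = var_by_name[target]
        ssq = sum(c.coef ** 2 for c in specs)
        mean = np.where(groups == GLAUCOMA, vspec.mean[GLAUCOMA], vspec.mean[CONTROL])
        sd = np.where(groups == GLAUCOMA, vspec.sd[GLAUCOMA], vspec.sd[CONTROL])
        resid = (data[target].to_numpy() - mean) / np.where(sd > 0, sd, 1.0)
        combined = math.sqrt(max(0.0, 1.0 - ssq)) * resid
        for c in specs:
            z = log_levels[c.analyte]
            z = (z - z.mean()) / z.std(ddof=0)
            combined = combined + c.coef * z
            coup[(c.analyte, target)] = c.coef
        data[target] = mean + sd * combined

    value_cols = [c for c in data.columns if c != GROUP_COLUMN]
    shape_frame = lambda: pd.DataFrame(False, index=index, columns=value_cols)

    # censoring at the detection limit
    censor_mask = shape_frame()
    for a in config.analytes:
        vals, detected = apply_lod_censoring(data[a.column].to_numpy(), a.lod)
        censor_mask[a.column] = ~detected
        data[a.column] = vals

    # heavy-tail contamination of continuous cells
    outlier_mask = shape_frame()
    if config.outlier_rate > 0:
        for col in value_cols:
            if meta[col].scale != "continuous":
                continue
            hit = rng_outlier.random(n) < config.outlier_rate
            hit &= ~censor_mask[col].to_numpy()
            if meta[col].is_analyte:
                data.loc[hit, col] = data.loc[hit, col] * config.outlier_scale
            else:
                center = data[col].mean()
                data.loc[hit, col] = center + (data.loc[hit, col] - center) * config.outlier_scale
            outlier_mask[col] = hit

    # missing completely at random; never on an already-censored cell
    missing_mask = shape_frame()
    if config.missing_rate > 0:
        for col in value_cols:
            hit = rng_missing.random(n) < config.missing_rate
            hit &= ~censor_mask[col].to_numpy()
            data.loc[hit, col] = np.nan
            missing_mask[col] = hit

    truth = GroundTruth(analyte_log2_fc=fc, coupling_coefs=coup,
                        outlier_mask=outlier_mask, missing_mask=missing_mask,
                        censor_mask=censor_mask, seed=config.seed)
    return CohortTable(data, meta), truth


# --------------------------------------------------------------------------
# default study conditions
# --------------------------------------------------------------------------

PANEL_35 = [
    "APN", "Angiogenin", "Angiopoietin-1", "Angiostatin", "Arginase-1",
    "BMP-2", "BMP-9", "BigET-1", "C3a", "CKMB", "CNTF", "Cortisol",
    "sEMMPRIN", "Endoglin", "Endostatin", "sE-Selectin", "Follistatin",
    "IL-6", "IL-8", "sLOX-1", "MCP-1", "MICB", "MMP-2", "MMP-3", "MMP-9",
    "NTproBNP", "PDGF-BB", "PlGF-1", "Resistin", "SAA", "Survivin",
    "sTIE-2", "TNF-alpha", "VEGF-A", "ZAG",
]
PANEL = ["ET-1"] + PANEL_35  # 36 analytes, measured in both compartments

# aqueous-humor analytes with a planted glaucoma elevation, plus plasma ET-1
ELEVATED_AQH = ["MMP-2", "MMP-3", "ET-1", "sEMMPRIN", "ZAG", "sLOX-1",
                "Follistatin", "Cortisol", "Endostatin", "sTIE-2", "PDGF-BB"]

_CLINICAL = [
    VariableSpec("Age", mean={CONTROL: 66.8, GLAUCOMA: 65.0},
                 sd={CONTROL: 9.0, GLAUCOMA: 11.9}),
    VariableSpec("Sex", scale="dichotomous",
                 categories={CONTROL: {"Female": 20 / 30, "Male": 10 / 30},
                             GLAUCOMA: {"Female": 48 / 87, "Male": 39 / 87}}),
    VariableSpec("IOP", mean={CONTROL: 13.3, GLAUCOMA: 19.3},
                 sd={CONTROL: 1.8, GLAUCOMA: 6.0}),
    VariableSpec("Topical_Beta_Blocker", scale="dichotomous",
                 categories={CONTROL: {0.0: 1.0, 1.0: 0.0},
                             GLAUCOMA: {0.0: 0.391, 1.0: 0.609}}),
    VariableSpec("Glaucoma_Entity", scale="nominal",
                 categories={CONTROL: {"NoGlaucoma": 1.0},
                             GLAUCOMA: {"POAG": 63 / 87, "XFG": 11 / 87, "NTG": 6 / 87,
                                        "PG": 2 / 87, "ACG": 3 / 87, "Unclassified": 2 / 87}}),
    VariableSpec("RNFL_Thickness", role="dependent-candidate",
                 mean={CONTROL: 96.79, GLAUCOMA: 74.32},
                 sd={CONTROL: 8.72, GLAUCOMA: 13.87}),
    VariableSpec("Ganglion_Cell_Complex", role="dependent-candidate",
                 mean={CONTROL: 96.55, GLAUCOMA: 77.6},
                 sd={CONTROL: 8.41, GLAUCOMA: 12.4}),
    VariableSpec("Global_Loss_Volume", mean={CONTROL: 2.6, GLAUCOMA: 17.97},
                 sd={CONTROL: 2.8, GLAUCOMA: 10.73}),
    VariableSpec("Cup_Disc_Ratio", mean={CONTROL: 0.31, GLAUCOMA: 0.65},
                 sd={CONTROL: 0.15, GLAUCOMA: 0.16}),
    VariableSpec("Rim_Area", mean={CONTROL: 1.37, GLAUCOMA: 0.75},
                 sd={CONTROL: 0.35, GLAUCOMA: 0.33}),
    VariableSpec("VD_ONH_Whole", mean={CONTROL: 47.00, GLAUCOMA: 35.97},
                 sd={CONTROL: 2.52, GLAUCOMA: 6.86}),
    VariableSpec("VD_PeriONH_Average", role="dependent-candidate",
                 mean={CONTROL: 47.5, GLAUCOMA: 36.5},
                 sd={CONTROL: 2.6, GLAUCOMA: 7.0}),
    VariableSpec("VD_Macula_SVP_Whole", role="dependent-candidate",
                 mean={CONTROL: 41.90, GLAUCOMA: 37.39},
                 sd={CONTROL: 4.15, GLAUCOMA: 4.40}),
    VariableSpec("VD_Fovea_SVP", mean={CONTROL: 19.99, GLAUCOMA: 17.0},
                 sd={CONTROL: 6.69, GLAUCOMA: 7.9}),
    VariableSpec("FAZ", mean={CONTROL: 0.26, GLAUCOMA: 0.27},
                 sd={CONTROL: 0.10, GLAUCOMA: 0.12}),
    VariableSpec("GSS_Score", role="dependent-candidate",
                 mean={CONTROL: 0.3, GLAUCOMA: 2.8},
                 sd={CONTROL: 0.5, GLAUCOMA: 1.3}),
]

_DEFAULT_COUPLINGS = [
    CouplingSpec("APN_AqH", "VD_PeriONH_Average", -0.45),
    CouplingSpec("C3a_AqH", "VD_PeriONH_Average", -0.35),
    CouplingSpec("MMP-3_AqH", "VD_PeriONH_Average", -0.35),
    CouplingSpec("Resistin_AqH", "VD_ONH_Whole", -0.35),
    CouplingSpec("sTIE-2_AqH", "VD_ONH_Whole", -0.35),
    CouplingSpec("ZAG_AqH", "VD_ONH_Whole", -0.35),
]


def default_config(seed: int = 0, *, outlier_rate: float = 0.02,
                   missing_rate: float = 0.05, planted_log2_fc: float = 1.0) -> SyntheticConfig:
    """Study-shaped defaults: 30 controls vs 87 glaucomatous eyes, 36 analytes
    per compartment, planted aqueous-humor elevations and analyte->perfusion
    couplings, mild contamination and missingness.

    Detection limits default to the 2nd percentile of each analyte's control
    log-normal (exp(mu - 2.054 sd)); the assays' true limits are not public.
    """
    analytes = []
    for i, name in enumerate(PANEL):
        for compartment in ("plasma", "AqH"):
            # spread baseline abundances over ~3 decades, deterministically
            log_mean = 2.0 + 5.0 * ((i * 7 + (compartment == "AqH") * 3) % 36) / 36.0
            log_sd = 0.5
            fc = 0.0
            if compartment == "AqH" and name in ELEVATED_AQH:
                fc = planted_log2_fc
            if compartment == "plasma" and name == "ET-1":
                fc = planted_log2_fc
            analytes.append(AnalyteSpec(
                name=name, compartment=compartment, log_mean=log_mean,
                log_sd=log_sd, lod=math.exp(log_mean - 2.054 * log_sd), log2_fc=fc))
    return SyntheticConfig(
        n_control=30, n_glaucoma=87, analytes=analytes, variables=list(_CLINICAL),
        couplings=list(_DEFAULT_COUPLINGS), outlier_rate=outlier_rate,
        outlier_scale=10.0, missing_rate=missing_rate, seed=seed)
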