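"""Seeded synthetic EMR cohort generator.

Each patient carries two latent modality scores ``u_struct`` and ``u_text``
(Rademacher ±1). They drive, respectively, mean shifts of the numeric lab
fields and the Bernoulli rates of label-linked tokens in the rendered text
units. The binary label follows a logistic model

    logit = b0 + struct_effect*u_struct + text_effect*u_text
               + interaction_effect*u_struct*u_text

with ``b0`` solved deterministically so the expected prevalence matches the
config. Because the latents are discrete, the Bayes-optimal accuracy of a
classifier that observes them is available in closed form
(:func:`bayes_accuracy`) and is used as an independent oracle in tests.

The full generate → summarize pipeline is a pure function of the config
(including its seed): same config, byte-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import brentq
from scipy.special import expit

from .schema import MISSING, Cohort, FeatureSchema, PatientRecord

#: Label-linked CT findings; presence probability depends on u_text.
CT_FINDING_TOKENS = ("emphysema", "bronchial wall thickening", "air trapping")
#: Label-neutral filler findings (report boilerplate drawn per record).
CT_FILLER_TOKENS = (
    "mild scarring", "calcified granuloma", "no pleural effusion",
    "heart size within normal limits", "no mediastinal lymphadenopathy",
    "degenerative changes of the thoracic spine", "aortic wall calcification",
    "no focal consolidation", "trachea midline", "no pneumothorax",
    "surgical clips in the right upper quadrant", "mild hiatal hernia",
    "atherosclerotic changes of the aorta", "no suspicious pulmonary nodule",
    "visualized upper abdomen unremarkable", "stable subcentimeter nodule",
)
HISTORY_SYMPTOMS = ("chronic cough", "sputum production", "exertional dyspnea", "wheezing")
HISTORY_FILLER = (
    "hypertension managed with medication", "type 2 diabetes mellitus",
    "no known drug allergies", "appendectomy in remote past",
    "denies chest pain", "reports intermittent fatigue",
    "lives with family", "retired factory worker", "no recent travel",
    "seasonal allergic rhinitis", "mild hearing loss", "cataract surgery",
)


class CohortConfig(BaseModel):
    n_patients: int = 800
    n_female: int = 276
    n_male: int = 524
    age_mean: float = 65.0
    age_sd: float = 10.0
    age_bounds: tuple[float, float] = (35.0, 91.0)
    prevalence: float = Field(default=0.45, ge=0.0, le=1.0)
    # log-odds scale effect sizes of the label model
    struct_effect: float = 1.5
    text_effect: float = 1.5
    interaction_effect: float = 0.0
    # P(u_text = u_struct) = (1 + latent_correlation) / 2
    latent_correlation: float = Field(default=0.0, ge=-1.0, le=1.0)
    fever_rate: float = Field(default=0.35, ge=0.0, le=1.0)
    # token expression fidelity: P(finding token | u_text = +1 / -1)
    token_rate_high: float = Field(default=0.85, ge=0.0, le=1.0)
    token_rate_low: float = Field(default=0.10, ge=0.0, le=1.0)
    missing_rate: float = Field(default=0.05, ge=0.0, le=1.0)  # labs other than CRP
    afebrile_crp_missing_rate: float = Field(default=0.6, ge=0.0, le=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check_counts(self):
        if self.n_female + self.n_male != self.n_patients:
            raise ValueError("n_female + n_male must equal n_patients")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        lo, hi = self.age_bounds
        if not lo < hi:
            raise ValueError("age bounds must be ordered")
        return self


@dataclass(frozen=True)
class LatentState:
    """Per-patient generative state, exposed for oracle-style tests."""

    u_struct: int  # ±1
    u_text: int  # ±1
    findings: tuple[str, ...]  # CT finding tokens present
    fever: bool
    p_label: float


def _combo_weights(config: CohortConfig):
    """Joint pmf of the latent pair under the configured correlation."""
    p_same = (1.0 + config.latent_correlation) / 2.0
    for us in (-1, 1):
        for ut in (-1, 1):
            w = 0.5 * (p_same if us == ut else 1.0 - p_same)
            yield us, ut, w


def solve_intercept(config: CohortConfig) -> float:
    """Intercept b0 with E[sigmoid(logit)] = prevalence over the 4 latent combos."""
    if config.prevalence in (0.0, 1.0):
        return -np.inf if config.prevalence == 0.0 else np.inf
    bs, bt, bi = config.struct_effect, config.text_effect, config.interaction_effect

    def mean_p(b0: float) -> float:
        return sum(
            w * expit(b0 + bs * us + bt * ut + bi * us * ut)
            for us, ut, w in _combo_weights(config)
        )

    return float(brentq(lambda b0: mean_p(b0) - config.prevalence, -50.0, 50.0, xtol=1e-12))


def label_probability(config: CohortConfig, u_struct: int, u_text: int) -> float:
    b0 = solve_intercept(config)
    if not np.isfinite(b0):
        return 0.0 if b0 < 0 else 1.0
    return float(
        expit(
            b0
            + config.struct_effect * u_struct
            + config.text_effect * u_text
            + config.interaction_effect * u_struct * u_text
        )
    )


def bayes_accuracy(config: CohortConfig) -> float:
    """Accuracy of the optimal classifier that observes both latents."""
    acc = 0.0
    for us, ut, w in _combo_weights(config):
        p = label_probability(config, us, ut)
        acc += w * max(p, 1.0 - p)
    return acc


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi, n) -> np.ndarray:
    """Rejection sampling; exact truncation, deterministic under the rng."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=max(n - filled, 16))
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


# base value, noise sd, and u_struct shift per numeric lab field
_LAB_MODEL = {
    "crp": (8.0, 3.0, 2.0),
    "ph": (7.40, 0.03, -0.02),
    "pao2": (82.0, 6.0, -10.0),
    "paco2": (42.0, 4.0, 7.0),
    "hco3": (25.0, 2.0, 1.5),
    "wbc": (8.0, 1.5, 1.8),
    "neut_pct": (62.0, 6.0, 7.0),
    "hgb": (135.0, 12.0, -4.0),
}


def render_text_unit(latent: LatentState, unit: str, seed: int) -> str:
    """Deterministic template realization of one text unit."""
    rng = np.random.default_rng(seed)
    if unit == "ct_report":
        findings = list(latent.findings)
        n_filler = int(rng.integers(4, 9))
        fillers = list(rng.choice(CT_FILLER_TOKENS, size=n_filler, replace=False))
        body = "; ".join(findings + fillers) if (findings or fillers) else "no acute abnormality"
        severity = rng.choice(("mild", "moderate", "extensive"))
        return f"Chest CT: {body}. {severity} chronic changes noted."
    if unit == "history":
        symptoms = [s for s in HISTORY_SYMPTOMS if rng.random() < 0.5]
        smoker = rng.random() < 0.55
        parts = []
        if smoker:
            parts.append(f"former smoker, {int(rng.integers(10, 60))} pack-years")
        if latent.fever:
            parts.append("recent fever")
        parts.extend(symptoms)
        n_filler = int(rng.integers(2, 6))
        parts.extend(rng.choice(HISTORY_FILLER, size=n_filler, replace=False))
        return "Patient history: " + ("; ".join(parts) if parts else "unremarkable") + "."
    raise KeyError(f"unknown text unit {unit!r}")


def generate_cohort(config: CohortConfig, schema: FeatureSchema | None = None) -> Cohort:
    """Generate a seeded cohort with a plantable cross-modal label signal.

    Returns a :class:`Cohort` whose records carry explicit MISSING markers
    (CRP is preferentially dropped for afebrile patients); latent states are
    attached as ``cohort.latents`` for oracle-style tests.
    """
    schema = schema or FeatureSchema.default()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    u_struct = rng.choice((-1, 1), size=n)
    same = rng.random(n) < (1.0 + config.latent_correlation) / 2.0
    u_text = np.where(same, u_struct, -u_struct)

    b0 = solve_intercept(config)
    if np.isfinite(b0):
        logits = (
            b0
            + config.struct_effect * u_struct
            + config.text_effect * u_text
            + config.interaction_effect * u_struct * u_text
        )
        p_label = expit(logits)
    else:
        p_label = np.full(n, config.prevalence)
    labels = (rng.random(n) < p_label).astype(int)

    sexes = np.array(["female"] * config.n_female + ["male"] * config.n_male)
    rng.shuffle(sexes)
    lo, hi = config.age_bounds
    ages = _truncated_normal(rng, config.age_mean, config.age_sd, lo, hi, n)
    fevers = rng.random(n) < config.fever_rate

    labs = {}
    for name, (base, sd, shift) in _LAB_MODEL.items():
        f = schema.numeric(name)
        raw = base + shift * u_struct + rng.normal(0.0, sd, size=n)
        labs[name] = np.clip(raw, f.valid_range[0], f.valid_range[1])

    finding_draws = rng.random((n, len(CT_FINDING_TOKENS)))
    rates = np.where(u_text[:, None] > 0, config.token_rate_high, config.token_rate_low)
    findings_present = finding_draws < rates

    # missingness masks (drawn before record assembly for reproducibility)
    lab_names = [f.name for f in schema.numeric_fields if f.name not in ("age", "crp")]
    miss_draws = {name: rng.random(n) < config.missing_rate for name in lab_names}
    crp_miss = rng.random(n) < config.afebrile_crp_missing_rate

    text_seeds = rng.integers(0, 2**31 - 1, size=(n, len(schema.text_units)))

    records: list[PatientRecord] = []
    latents: list[LatentState] = []
    for i in range(n):
        findings = tuple(
            t for j, t in enumerate(CT_FINDING_TOKENS) if findings_present[i, j]
        )
        latent = LatentState(
            u_struct=int(u_struct[i]),
            u_text=int(u_text[i]),
            findings=findings,
            fever=bool(fevers[i]),
            p_label=float(p_label[i]),
        )
        values: dict = {
            "sex": str(sexes[i]),
            "fever": "yes" if fevers[i] else "no",
            "age": float(round(ages[i], 1)),
        }
        for name in _LAB_MODEL:
            values[name] = float(round(labs[name][i], 3))
        # mask AFTER assembly so pre-mask values validate cleanly
        for name in lab_names:
            if miss_draws[name][i]:
                values[name] = MISSING
        if not fevers[i] and crp_miss[i]:
            values["crp"] = MISSING
        text = {
            unit: render_text_unit(latent, unit, int(text_seeds[i, k]))
            for k, unit in enumerate(schema.text_units)
        }
        records.append(
            PatientRecord(
                id=f"P{i:05d}", values=values, text=text, label=int(labels[i])
            )
        )
        latents.append(latent)

    cohort = Cohort(records, schema)
    cohort.latents = latents  # type: ignore[attr-defined]
    return cohort


def cohort_summary(cohort: Cohort) -> pd.DataFrame:
    """Per-field missingness, label prevalence, sex/age distribution, lab moments."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    n = len(cohort)
    rows = [
        {"statistic": "n_patients", "value": float(n)},
        {"statistic": "label_prevalence", "value": float(cohort.labels().mean())},
    ]
    sexes = [r.values.get("sex") for r in cohort]
    rows.append({"statistic": "n_male", "value": float(sum(s == "male" for s in sexes))})
    rows.append({"statistic": "n_female", "value": float(sum(s == "female" for s in sexes))})
    for f in cohort.schema.numeric_fields:
        vals = [r.values[f.name] for r in cohort if r.values.get(f.name) is not MISSING]
        missing = n - len(vals)
        rows.append({"statistic": f"{f.name}_missing_rate", "value": missing / n})
        if vals:
            rows.append({"statistic": f"{f.name}_mean", "value": float(np.mean(vals))})
            rows.append({"statistic": f"{f.name}_sd", "value": float(np.std(vals))})
    for f in cohort.schema.categorical_fields:
        vals = [r.values.get(f.name) for r in cohort]
        missing = sum(v is MISSING for v in vals)
        rows.append({"statistic": f"{f.name}_missing_rate", "value": missing / n})
    return pd.DataFrame(rows)
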