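"""Synthetic JADER-layout report generator with known ground truth.

Emulates the statistical structure of a spontaneous reporting database:
per-case demographics with field-level missingness, multiple drug rows per
case with involvement labels, multiple adverse-event rows per case,
duplicated rows, and designed drug–event association strengths plus
demographic effects on event risk. Every downstream stage (cleaning, signal
detection, logistic modelling, event profiling) can therefore be tested for
parameter recovery without any external data.

The generative model per case i and event e is

    logit P(event_e) = base_e + sum_d X_id * beta_de
                       + female_i * b_F + (age_i - 60) * b_A
                       + (height_i - 160) * b_H

with drug exposures X_id Bernoulli (independent by default, optionally
Gaussian-copula correlated to emulate co-prescription), so the designed
odds ratio for pair (d, e) is exp(beta_de). Age and height enter centred so
that `base_e` stays interpretable as (approximately) the logit of the
marginal event rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .errors import ConfigurationError
from .tables import write_jader_table

#: the 13 preferred terms of the osteonecrosis standardised MedDRA query
#: used for adverse-event profiling
OSTEONECROSIS_SMQ_TERMS = [
    "osteonecrosis of the jaw",
    "osteonecrosis",
    "osteomyelitis",
    "atypical femoral fracture",
    "bone pain",
    "pain in jaw",
    "jaw abscess",
    "osteitis",
    "tooth abscess",
    "bacterial osteomyelitis",
    "osteonecrosis of external auditory canal",
    "groin pain",
    "alveolar osteitis",
]

_COVARIATE_KEYS = ("female", "age_per_year", "height_per_cm")
_DEMO_FIELDS = ("sex", "age", "height", "weight")


@dataclass
class SynthConfig:
    """Full specification of one synthetic reporting database.

    Parameters
    ----------
    n_cases : int
        Number of case reports.
    drugs : dict
        Drug name -> marginal exposure probability.
    events : list of str
        Adverse-event preferred terms.
    baseline_event_logit : float or dict
        Baseline log-odds of each event (single value, or per-event dict).
    drug_effects : dict
        (drug, event) -> log odds ratio. Unlisted pairs are null.
    covariate_effects : dict
        Keys among {"female", "age_per_year", "height_per_cm"} -> log odds
        ratio per unit, applied to every event. Age/height are centred at
        60 years / 160 cm.
    missingness : float or dict
        Per-field probability that a DEMO field is blank.
    duplicate_rate : float
        Fraction of DRUG and REAC rows duplicated as exact copies.
    concomitant_rate : float
        Probability that a case carries one extra non-suspected drug row.
    exposure_corr : float or None
        Exchangeable Gaussian-copula correlation between drug exposures
        (models co-prescription); None/0 means independent.
    age_as_band : bool
        Emit age as decade bands ("70s") instead of exact years.
    """

    n_cases: int
    drugs: dict
    events: list
    baseline_event_logit: float | dict = -5.8
    drug_effects: dict = field(default_factory=dict)
    covariate_effects: dict = field(default_factory=dict)
    missingness: float | dict = 0.0
    duplicate_rate: float = 0.0
    concomitant_rate: float = 0.0
    exposure_corr: float | None = None
    age_as_band: bool = False
    seed: int = 0
    # demographic distributions (means near a frail, elderly-skewed
    # reporting population: ~49% female, mean age 60, heights/weights by sex)
    female_prob: float = 0.49
    age_mean: float = 60.0
    age_sd: float = 21.0
    height_mean: dict = field(default_factory=lambda: {"female": 154.0, "male": 167.0})
    height_sd: dict = field(default_factory=lambda: {"female": 7.0, "male": 7.0})
    weight_mean: dict = field(default_factory=lambda: {"female": 52.0, "male": 64.0})
    weight_sd: dict = field(default_factory=lambda: {"female": 10.0, "male": 11.0})
    height_weight_corr: float = 0.5

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ConfigurationError("n_cases must be >= 1")
        for name, p in self.drugs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"exposure probability for {name!r}: {p}")
        for key in self.drug_effects:
            d, e = key
            if d not in self.drugs:
                raise ConfigurationError(f"drug_effects references unknown drug {d!r}")
            if e not in self.events:
                raise ConfigurationError(f"drug_effects references unknown event {e!r}")
        for key in self.covariate_effects:
            if key not in _COVARIATE_KEYS:
                raise ConfigurationError(
                    f"unknown covariate {key!r}; expected one of {_COVARIATE_KEYS}")
        miss = self.missingness
        probs = list(miss.values()) if isinstance(miss, dict) else [miss]
        for p in probs + [self.duplicate_rate, self.concomitant_rate,
                          self.female_prob]:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"probability out of [0,1]: {p}")
        if self.exposure_corr is not None and not -0.99 < self.exposure_corr < 0.99:
            raise ConfigurationError("exposure_corr must be in (-0.99, 0.99)")

    def baseline_for(self, event: str) -> float:
        if isinstance(self.baseline_event_logit, dict):
            return float(self.baseline_event_logit[event])
        return float(self.baseline_event_logit)

    def missing_prob(self, field_name: str) -> float:
        if isinstance(self.missingness, dict):
            return float(self.missingness.get(field_name, 0.0))
        return float(self.missingness)


@dataclass
class GroundTruth:
    """Latent per-case state and designed effect sizes behind one dataset."""

    designed_or: dict           # (drug, event) -> odds ratio
    exposure: pd.DataFrame      # case x drug booleans
    event_ind: pd.DataFrame     # case x event booleans
    demo_true: pd.DataFrame     # case-level sex/age/height/weight before missingness


def _sample_demographics(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_cases
    female = rng.random(n) < cfg.female_prob
    a, b = (0.0 - cfg.age_mean) / cfg.age_sd, (100.0 - cfg.age_mean) / cfg.age_sd
    age = stats.truncnorm.rvs(a, b, loc=cfg.age_mean, scale=cfg.age_sd,
                              size=n, random_state=rng)
    sex_key = np.where(female, "female", "male")
    h_mean = np.where(female, cfg.height_mean["female"], cfg.height_mean["male"])
    h_sd = np.where(female, cfg.height_sd["female"], cfg.height_sd["male"])
    w_mean = np.where(female, cfg.weight_mean["female"], cfg.weight_mean["male"])
    w_sd = np.where(female, cfg.weight_sd["female"], cfg.weight_sd["male"])
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    rho = cfg.height_weight_corr
    height = h_mean + h_sd * z1
    weight = w_mean + w_sd * (rho * z1 + np.sqrt(1 - rho ** 2) * z2)
    weight = np.clip(weight, 2.0, None)
    height = np.clip(height, 40.0, None)
    return pd.DataFrame({
        "sex": sex_key, "age": age, "height": height, "weight": weight,
        "female": female.astype(float),
    })


def _sample_exposures(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    n, names = cfg.n_cases, list(cfg.drugs)
    probs = np.array([cfg.drugs[d] for d in names])
    if cfg.exposure_corr:
        rho = cfg.exposure_corr
        d = len(names)
        shared = rng.standard_normal((n, 1))
        own = rng.standard_normal((n, d))
        z = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own
        return z < stats.norm.ppf(probs)
    return rng.random((n, len(names))) < probs


def generate(config: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate DRUG/REAC/DEMO tables plus ground truth from a config.

    Fully reproducible: identical configs (including seed) yield identical
    outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    drug_names = list(config.drugs)
    event_names = list(config.events)
    case_ids = np.array([f"C{i:07d}" for i in range(n)])

    demo_true = _sample_demographics(config, rng)
    exposure = _sample_exposures(config, rng)

    beta = np.zeros((len(drug_names), len(event_names)))
    for (d, e), val in config.drug_effects.items():
        beta[drug_names.index(d), event_names.index(e)] = val
    base = np.array([config.baseline_for(e) for e in event_names])
    logit = base + exposure @ beta
    cov = config.covariate_effects
    cov_term = (cov.get("female", 0.0) * demo_true["female"].to_numpy()
                + cov.get("age_per_year", 0.0) * (demo_true["age"].to_numpy() - 60.0)
                + cov.get("height_per_cm", 0.0) * (demo_true["height"].to_numpy() - 160.0))
    logit = logit + cov_term[:, None]
    event_ind = rng.random(logit.shape) < expit(logit)

    # --- DRUG table: suspected rows from exposures, optional concomitants
    ci, di = np.nonzero(exposure)
    drug_df = pd.DataFrame({
        "case_id": case_ids[ci],
        "drug_name": np.array(drug_names, dtype=object)[di],
        "involvement": "suspected",
    })
    if config.concomitant_rate > 0 and drug_names:
        has_conc = rng.random(n) < config.concomitant_rate
        idx = np.nonzero(has_conc)[0]
        picks = rng.integers(0, len(drug_names), size=len(idx))
        conc = pd.DataFrame({
            "case_id": case_ids[idx],
            "drug_name": np.array(drug_names, dtype=object)[picks],
            "involvement": "concomitant",
        })
        drug_df = pd.concat([drug_df, conc], ignore_index=True)

    # --- REAC table
    ci, ei = np.nonzero(event_ind)
    reac_df = pd.DataFrame({
        "case_id": case_ids[ci],
        "pt_name": np.array(event_names, dtype=object)[ei],
    })

    # --- exact-copy duplicates
    if config.duplicate_rate > 0:
        for df in (drug_df, reac_df):
            k = int(np.floor(config.duplicate_rate * len(df)))
            if k:
                picks = rng.choice(len(df), size=k, replace=False)
                dup = df.iloc[np.sort(picks)]
                df_new = pd.concat([df, dup], ignore_index=True)
                if df is drug_df:
                    drug_df = df_new
                else:
                    reac_df = df_new

    # --- DEMO table with field-level missingness
    age_raw = np.floor(demo_true["age"].to_numpy()).astype(int)
    if config.age_as_band:
        age_str = np.array([f"{(a // 10) * 10}s" for a in age_raw], dtype=object)
    else:
        age_str = age_raw.astype(str).astype(object)
    weight = demo_true["weight"].to_numpy()
    weight_str = np.where(weight > 60.0, ">60",
                          np.where(weight < 10.0, "<10",
                                   np.round(weight).astype(int).astype(str))).astype(object)
    height_str = np.round(demo_true["height"].to_numpy(), 1).astype(str).astype(object)
    demo_df = pd.DataFrame({
        "case_id": case_ids,
        "sex": demo_true["sex"].to_numpy(dtype=object),
        "age": age_str,
        "height": height_str,
        "weight": weight_str,
    })
    for fname in _DEMO_FIELDS:
        p = config.missing_prob(fname)
        if p > 0:
            mask = rng.random(n) < p
            demo_df.loc[mask, fname] = ""

    truth = GroundTruth(
        designed_or={k: float(np.exp(v)) for k, v in config.drug_effects.items()},
        exposure=pd.DataFrame(exposure, index=case_ids, columns=drug_names),
        event_ind=pd.DataFrame(event_ind, index=case_ids, columns=event_names),
        demo_true=demo_true.assign(case_id=case_ids),
    )
    return drug_df, reac_df, demo_df, truth


def write_tables(tables, out_dir, truth: GroundTruth | None = None) -> dict:
    """Write generated tables (and designed effect sizes) under `out_dir`.

    Returns a dict of written paths; files are readable by
    :func:`jaderpv.tables.read_jader_table` with the default column map.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    drug_df, reac_df, demo_df = tables[:3]
    paths = {
        "DRUG": out_dir / "drug.csv",
        "REAC": out_dir / "reac.csv",
        "DEMO": out_dir / "demo.csv",
    }
    write_jader_table(drug_df, paths["DRUG"], "DRUG")
    write_jader_table(reac_df, paths["REAC"], "REAC")
    write_jader_table(demo_df, paths["DEMO"], "DEMO")
    if truth is not None:
        gt_path = out_dir / "ground_truth.json"
        with open(gt_path, "w", encoding="utf-8") as fh:
            json.dump({f"{d}|{e}": v for (d, e), v in truth.designed_or.items()},
                      fh, indent=2, sort_keys=True)
        paths["ground_truth"] = gt_path
    return {k: str(v) for k, v in paths.items()}


# --- canonical study-like configurations -----------------------------------

#: antiresorptive agents act through osteoclast suppression and drive the
#: jaw-osteonecrosis / femoral-fracture / osteomyelitis / osteonecrosis block
ANTIRESORPTIVE_DRUGS = {
    "zoledronate": 0.020,
    "alendronate": 0.015,
    "denosumab": 0.012,
    "risedronate": 0.010,
}
#: comparator drugs with infection/pain-type bone events
OTHER_DRUGS = {
    "prednisolone": 0.050,
    "sunitinib": 0.010,
    "letrozole": 0.010,
    "methotrexate": 0.030,
}

OSTEOCLAST_EVENTS = [
    "osteonecrosis of the jaw",
    "atypical femoral fracture",
    "osteomyelitis",
    "osteonecrosis",
]


def default_study_config(n_cases: int = 50_000, seed: int = 0) -> SynthConfig:
    """A study-scale configuration emulating an osteonecrosis safety signal.

    Two latent mechanisms drive the 13 osteonecrosis-query events:
    antiresorptive drugs load the osteoclast-mediated block (jaw
    osteonecrosis at log-OR ln 20, femoral fracture ln 12, osteomyelitis and
    osteonecrosis ln 6), while comparator drugs load the infection/pain
    block. Demographic risk mirrors the known profile: female (ln 1.3),
    older age (ln 1.02 per year), shorter stature (ln 0.99 per cm).
    """
    events = list(OSTEONECROSIS_SMQ_TERMS)
    baselines = {e: float(np.log(0.0008 / (1 - 0.0008))) for e in events}
    for e, rate in {"osteonecrosis of the jaw": 0.003,
                    "osteonecrosis": 0.001,
                    "osteomyelitis": 0.001,
                    "atypical femoral fracture": 0.001}.items():
        baselines[e] = float(np.log(rate / (1 - rate)))
    other_events = [e for e in events if e not in OSTEOCLAST_EVENTS]

    drug_effects: dict = {}
    osteo_strength = {
        "osteonecrosis of the jaw": np.log(20.0),
        "atypical femoral fracture": np.log(12.0),
        "osteomyelitis": np.log(6.0),
        "osteonecrosis": np.log(6.0),
    }
    for d in ANTIRESORPTIVE_DRUGS:
        for e, b in osteo_strength.items():
            drug_effects[(d, e)] = float(b)
    for d in OTHER_DRUGS:
        for e in other_events:
            drug_effects[(d, e)] = float(np.log(6.0))
        # comparators carry a mild jaw-osteonecrosis risk (confounded signal)
        drug_effects[(d, "osteonecrosis of the jaw")] = float(np.log(1.5))

    return SynthConfig(
        n_cases=n_cases,
        drugs={**ANTIRESORPTIVE_DRUGS, **OTHER_DRUGS},
        events=events,
        baseline_event_logit=baselines,
        drug_effects=drug_effects,
        covariate_effects={"female": float(np.log(1.3)),
                           "age_per_year": float(np.log(1.02)),
                           "height_per_cm": float(np.log(0.99))},
        missingness={"sex": 0.03, "age": 0.07, "height": 0.55, "weight": 0.48},
        duplicate_rate=0.05,
        concomitant_rate=0.10,
        seed=seed,
    )


def config_from_dict(d: dict) -> SynthConfig:
    """Build a SynthConfig from a parsed YAML/JSON mapping.

    `drug_effects` keys may be "drug|event" strings (file-friendly form).
    """
    d = dict(d)
    if "drug_effects" in d:
        eff = {}
        for k, v in d["drug_effects"].items():
            key = tuple(k.split("|")) if isinstance(k, str) else tuple(k)
            eff[key] = float(v)
        d["drug_effects"] = eff
    return SynthConfig(**d)
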