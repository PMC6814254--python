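"""Synthetic longitudinal claims with the structure the analysis assumes.

The generator emulates a commercially insured opioid-using population
observed quarterly: a minority of "at-risk" prescribers around whom
doctor shopping concentrates, a latent shopper stratum that
preferentially attaches to them (producing a right-skewed, hub-heavy
shared-prescriber degree distribution), MAT fills to exercise the
exclusion filter, and ICD-10 diagnosis codes for the outcome and
control definitions.

Generation is two-stage.  Stage one draws the population and the raw
prescription/diagnosis tables; stage two (:func:`plant_outcomes`) runs
the network pass on the realized claims and then generates the four
outcomes from a known linear predictor in the realized between/within
prominence terms plus a patient random intercept — so that the panel
models can be tested for parameter recovery against planted truth.
Everything is driven by one root seed through documented stream
splitting, and reruns are byte-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .centrality import CentralityParams, centrality_table
from .network import filter_opioid_claims
from .panel_models import decompose

__all__ = [
    "ConfigError",
    "SynthConfig",
    "DRUG_MME",
    "MAT_DRUG",
    "generate_population",
    "generate_claims",
    "plant_outcomes",
    "generate_study",
    "simulate_panel",
    "write_tables",
    "read_tables",
]

#: CDC-style oral MME conversion factors for the shipped drug dictionary
DRUG_MME = {
    "hydrocodone": 1.0,
    "oxycodone": 1.5,
    "morphine": 1.0,
    "fentanyl_patch": 2.4,
    "codeine": 0.15,
}
MAT_DRUG = "buprenorphine"            # excluded from network construction

OUTCOMES = ("n_rx", "mme_gt90", "overdose_any", "oud")

_OPIOIDS = list(DRUG_MME)
_OPIOID_P = np.array([0.40, 0.35, 0.13, 0.05, 0.07])
_FILLER_CODES = ["J06.9", "M54.5", "I10", "E11.9", "K21.9"]
_OVERDOSE_CODES = ["T40.2X1A", "T50.901A"]     # opioid / unspecified, accidental
_OUD_CODE = "F11.20"
_CANCER_CODE = "C50.911"

#: demographic marginals of the simulated region (female share, age
#: mean/SD, insurance mix, state mix) — chosen to mirror a commercially
#: insured Appalachian-region opioid cohort
FEMALE_SHARE = 0.5867
AGE_MEAN, AGE_SD = 55.98, 17.17
INSURANCE_P = {"HMO": 0.1692, "POS": 0.4306, "Other": 0.4002}
STATE_P = {
    "GA": 0.3150, "KY": 0.0310, "NC": 0.2727, "OH": 0.1891,
    "TN": 0.1032, "VA": 0.0834, "WV": 0.0056,
}
CANCER_SHARE = 0.138


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


def _log(x: float) -> float:
    return math.log(x)


@dataclass
class SynthConfig:
    """All knobs of the generator, with study-condition defaults.

    Effects are planted on the log-odds (or log-rate) scale per 10
    percentile points of prominence, split into between-person (bp) and
    within-person (wp) components; defaults are realistic magnitudes
    for an opioid claims panel (count IRRs near 1.15–1.2, odds ratios
    up to ~2 for the rarest outcomes).
    """

    n_patients: int = 2000
    n_prescribers: int = 250
    n_quarters: int = 7
    n_panel_quarters: int = 4
    frac_at_risk_prescribers: float = 0.13
    frac_shopper_patients: float = 0.10
    mat_fraction: float = 0.02            # patient-quarters with a MAT fill
    shopper_visit_rate: float = 3.0       # prescriber visits per quarter
    nonshopper_visit_rate: float = 0.5
    at_risk_preference: float = 25.0      # attachment weight multiplier
    prescriber_popularity_sigma: float = 1.0
    extra_fills_rate: float = 0.3         # extra fills per visited prescriber
    filler_dx_rate: float = 0.3
    baseline_rates: dict = field(
        default_factory=lambda: {
            "n_rx": 1.26, "mme_gt90": 0.0806, "overdose_any": 0.0016, "oud": 0.0116,
        }
    )
    prominence_effect_logodds: dict = field(
        default_factory=lambda: {
            "n_rx": {"bp": _log(1.18), "wp": _log(1.15)},
            "mme_gt90": {"bp": _log(1.88), "wp": _log(1.27)},
            "overdose_any": {"bp": _log(1.20), "wp": _log(1.10)},
            "oud": {"bp": _log(2.00), "wp": _log(1.11)},
        }
    )
    control_effects: dict = field(default_factory=dict)   # outcome -> {col: beta}
    dispersion: float = 0.8               # NB overdispersion of the count outcome
    sigma_u: dict = field(
        default_factory=lambda: {
            "n_rx": 1.0, "mme_gt90": 2.0, "overdose_any": 1.0, "oud": 2.0,
        }
    )
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_at_risk_prescribers", "frac_shopper_patients", "mat_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_patients", "n_prescribers"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if self.n_quarters < 3:
            raise ConfigError(
                f"n_quarters must be >= 3 so the pooling window fits, got {self.n_quarters}"
            )
        if not 1 <= self.n_panel_quarters <= self.n_quarters:
            raise ConfigError("n_panel_quarters must be in [1, n_quarters]")
        if self.dispersion <= 0:
            raise ConfigError(f"dispersion must be > 0, got {self.dispersion}")
        for o, s in self.sigma_u.items():
            if s < 0:
                raise ConfigError(f"sigma_u[{o!r}] must be >= 0, got {s}")
        for o in OUTCOMES:
            if o not in self.baseline_rates:
                raise ConfigError(f"baseline_rates missing outcome {o!r}")

    @property
    def panel_quarters(self) -> list[int]:
        """The analysis panel: the last n_panel_quarters of the window."""
        return list(range(self.n_quarters - self.n_panel_quarters, self.n_quarters))

    def rngs(self, n: int = 3):
        ss = np.random.SeedSequence(self.seed)
        return [np.random.default_rng(c) for c in ss.spawn(n)]


def generate_population(config: SynthConfig):
    """Draw patients and prescribers with exact latent-stratum counts.

    Exactly round(frac * n) patients are flagged latent shoppers and
    round(frac * n) prescribers flagged at-risk (a fixed-margin design,
    so tiny populations still contain both strata).  Latent columns
    (``latent_shopper``, per-outcome ``u_*`` intercepts) are ground
    truth for tests only and are never read by the analysis stages.
    """
    config.validate()
    rng = config.rngs(3)[0]
    n, m = config.n_patients, config.n_prescribers

    shopper = np.zeros(n, dtype=int)
    k = int(round(config.frac_shopper_patients * n))
    shopper[rng.choice(n, size=k, replace=False)] = 1

    ins_levels = list(INSURANCE_P)
    st_levels = list(STATE_P)
    patients = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "female": (rng.random(n) < FEMALE_SHARE).astype(int),
            "age_years": np.clip(rng.normal(AGE_MEAN, AGE_SD, n), 18.0, 95.0),
            "insurance": rng.choice(ins_levels, size=n, p=list(INSURANCE_P.values())),
            "state": rng.choice(st_levels, size=n, p=list(STATE_P.values())),
            "cancer_latent": (rng.random(n) < CANCER_SHARE).astype(int),
            "latent_shopper": shopper,
        }
    )
    for o in OUTCOMES:
        patients[f"u_{o}"] = rng.normal(0.0, config.sigma_u[o], n)

    at_risk = np.zeros(m, dtype=int)
    k = int(round(config.frac_at_risk_prescribers * m))
    at_risk[rng.choice(m, size=k, replace=False)] = 1
    prescribers = pd.DataFrame(
        {
            "prescriber_id": [f"D{i:05d}" for i in range(m)],
            "at_risk": at_risk,
            "popularity": rng.lognormal(0.0, config.prescriber_popularity_sigma, m),
        }
    )
    return patients, prescribers


def generate_claims(patients: pd.DataFrame, prescribers: pd.DataFrame, config: SynthConfig):
    """Draw prescription and diagnosis tables for every quarter.

    Shoppers visit prescribers at a higher rate and attach
    preferentially to at-risk prescribers (preferential attachment by
    popularity x at-risk weight), which concentrates shared-prescriber
    ties and right-skews the projected degree distribution.  Outcome
    diagnosis codes are NOT generated here — they are planted later,
    conditional on realized network prominence (see
    :func:`plant_outcomes`); this stage only emits filler and cancer
    codes plus MAT fills for the exclusion filter.
    """
    rng = config.rngs(3)[1]
    n, m = len(patients), len(prescribers)
    shopper = patients["latent_shopper"].to_numpy() == 1
    pop = prescribers["popularity"].to_numpy()
    at_risk = prescribers["at_risk"].to_numpy() == 1

    w_shop = pop * np.where(at_risk, config.at_risk_preference, 1.0)
    p_shop = w_shop / w_shop.sum()
    p_norm = pop / pop.sum()
    lam = np.where(shopper, config.shopper_visit_rate, config.nonshopper_visit_rate)

    pid = patients["patient_id"].to_numpy()
    did = prescribers["prescriber_id"].to_numpy()

    rx_parts, dx_parts = [], []
    for q in range(config.n_quarters):
        nvis = rng.poisson(lam)
        pieces = []
        for mask, p in ((shopper, p_shop), (~shopper, p_norm)):
            tot = int(nvis[mask].sum())
            if tot == 0:
                continue
            pieces.append(
                pd.DataFrame(
                    {
                        "patient_id": np.repeat(pid[mask], nvis[mask]),
                        "prescriber_id": did[rng.choice(m, size=tot, p=p)],
                    }
                )
            )
        if pieces:
            pairs = pd.concat(pieces, ignore_index=True).drop_duplicates()
            nfills = 1 + rng.poisson(config.extra_fills_rate, len(pairs))
            rows = pairs.loc[pairs.index.repeat(nfills)].reset_index(drop=True)
            nr = len(rows)
            drugs = rng.choice(_OPIOIDS, size=nr, p=_OPIOID_P)
            rows["drug_code"] = drugs
            rows["quarter"] = q
            rows["daily_dose_mg"] = rng.uniform(5.0, 15.0, nr).round(2)
            rows["mme_factor"] = [DRUG_MME[d] for d in drugs]
            rows["fill_day"] = rng.integers(0, 90, nr)
            rows["days_supply"] = 30
            rows["is_mat"] = 0
            rx_parts.append(rows)

        mat_mask = rng.random(n) < config.mat_fraction
        nm = int(mat_mask.sum())
        if nm:
            rx_parts.append(
                pd.DataFrame(
                    {
                        "patient_id": pid[mat_mask],
                        "prescriber_id": did[rng.integers(0, m, nm)],
                        "drug_code": MAT_DRUG,
                        "quarter": q,
                        "daily_dose_mg": 8.0,
                        "mme_factor": 1.0,
                        "fill_day": rng.integers(0, 90, nm),
                        "days_supply": 30,
                        "is_mat": 1,
                    }
                )
            )

        dx_mask = rng.random(n) < config.filler_dx_rate
        nd = int(dx_mask.sum())
        if nd:
            dx_parts.append(
                pd.DataFrame(
                    {
                        "patient_id": pid[dx_mask],
                        "quarter": q,
                        "icd10_code": rng.choice(_FILLER_CODES, size=nd),
                    }
                )
            )

    cancer = patients.loc[patients["cancer_latent"] == 1, "patient_id"]
    if len(cancer):
        dx_parts.append(
            pd.DataFrame(
                {
                    "patient_id": cancer.to_numpy(),
                    "quarter": rng.integers(0, config.n_quarters, len(cancer)),
                    "icd10_code": _CANCER_CODE,
                }
            )
        )

    cols = ["patient_id", "prescriber_id", "drug_code", "quarter", "daily_dose_mg",
            "mme_factor", "fill_day", "days_supply", "is_mat"]
    rx = (
        pd.concat(rx_parts, ignore_index=True)[cols]
        if rx_parts
        else pd.DataFrame(columns=cols)
    )
    dx = (
        pd.concat(dx_parts, ignore_index=True)
        if dx_parts
        else pd.DataFrame(columns=["patient_id", "quarter", "icd10_code"])
    )
    return rx, dx


def _calibrate_logit(eta0: np.ndarray, target: float) -> float:
    """Intercept a such that mean(expit(a + eta0)) == target, in-sample."""
    target = min(max(target, 1e-8), 0.95)

    def f(a):
        return expit(a + eta0).mean() - target

    return brentq(f, -30.0, 15.0, xtol=1e-12)


def plant_outcomes(
    patients: pd.DataFrame,
    rx: pd.DataFrame,
    dx: pd.DataFrame,
    centrality: pd.DataFrame,
    config: SynthConfig,
):
    """Generate the four outcomes from realized network prominence.

    For each outcome o the linear predictor over panel rows is

        eta = a_o + b_bp (bp - 5) + b_wp wp + controls + u_i

    with bp/wp the realized between/within PageRank-percentile terms
    (per 10 points; bp is centered at its 5.0 expectation so a_o stays
    interpretable) and u_i the patient's planted random intercept.  The
    intercept a_o is calibrated in-sample so the marginal outcome rate
    matches ``baseline_rates`` — the generator's rates are design
    targets, not emergent.

    Materialization back into claims keeps the realized network fixed:
    OUD and overdose become ICD-10 codes in the diagnosis table; the
    prescription count is planted as NB draws realized by duplicating /
    trimming fills while preserving at least one fill per existing
    (patient, prescriber) pair (so the count is floor-censored at the
    prescriber count); the MME flag boosts the dose of one existing
    fill to 150 mg morphine-equivalent.  Count and MME planting apply
    only to patient-quarters with at least one opioid fill.

    Returns ``(rx_aug, dx_aug, truth)`` where ``truth`` carries the
    planted parameters and per-row planted outcomes; analysis stages
    must never read it.
    """
    if centrality is None or "pr_pct" not in centrality.columns:
        raise ValueError("plant_outcomes requires a centrality table with pr_pct; "
                         "run the network/centrality pass first")
    rng = config.rngs(3)[2]
    panel_q = config.panel_quarters

    cent = centrality.loc[centrality["quarter"].isin(panel_q),
                          ["patient_id", "quarter", "pr_pct"]].copy()
    cent = decompose(cent, column="pr_pct", group="patient_id", scale=10.0)
    base = cent.merge(patients, on="patient_id", how="left")

    rx_f = filter_opioid_claims(rx)
    rx_panel = rx_f.loc[rx_f["quarter"].isin(panel_q)]
    grp = rx_panel.groupby(["patient_id", "quarter"])
    expo = grp.agg(
        n_fills=("prescriber_id", "size"), n_prescribers=("prescriber_id", "nunique")
    ).reset_index()
    base = base.merge(expo, on=["patient_id", "quarter"], how="left")
    base["n_fills"] = base["n_fills"].fillna(0).astype(int)
    base["n_prescribers"] = base["n_prescribers"].fillna(0).astype(int)
    eligible = base["n_fills"].to_numpy() > 0

    truth_panel = base[["patient_id", "quarter", "bp", "wp"]].copy()
    betas, intercepts = {}, {}
    n_rows = len(base)

    def eta_without_intercept(outcome):
        b = config.prominence_effect_logodds[outcome]
        eta = (
            b["bp"] * (base["bp"].to_numpy() - 5.0)
            + b["wp"] * base["wp"].to_numpy()
            + base[f"u_{outcome}"].to_numpy()
        )
        for col, beta in config.control_effects.get(outcome, {}).items():
            eta = eta + beta * base[col].to_numpy(dtype=float)
        betas[outcome] = dict(b)
        return eta

    # --- binary outcomes realized through diagnosis codes -----------------
    dx_new = []
    for outcome, codes in (("oud", [_OUD_CODE]), ("overdose_any", _OVERDOSE_CODES)):
        eta0 = eta_without_intercept(outcome)
        a = _calibrate_logit(eta0, config.baseline_rates[outcome])
        intercepts[outcome] = a
        yvec = (rng.random(n_rows) < expit(a + eta0)).astype(int)
        truth_panel[f"y_{outcome}"] = yvec
        hit = np.flatnonzero(yvec)
        if len(hit):
            if len(codes) == 1:
                code_draw = np.repeat(codes[0], len(hit))
            else:
                code_draw = np.where(
                    rng.random(len(hit)) < 0.8, codes[0], codes[1]
                )
            dx_new.append(
                pd.DataFrame(
                    {
                        "patient_id": base["patient_id"].to_numpy()[hit],
                        "quarter": base["quarter"].to_numpy()[hit],
                        "icd10_code": code_draw,
                    }
                )
            )

    # --- MME > 90 flag, only where an opioid fill exists ------------------
    eta0 = eta_without_intercept("mme_gt90")
    n_elig = int(eligible.sum())
    target = config.baseline_rates["mme_gt90"]
    adj_target = target * n_rows / max(n_elig, 1)
    a = _calibrate_logit(eta0[eligible], adj_target) if n_elig else float("nan")
    intercepts["mme_gt90"] = a
    y_mme = np.zeros(n_rows, dtype=int)
    if n_elig:
        y_mme[eligible] = (
            rng.random(n_elig) < expit(a + eta0[eligible])
        ).astype(int)
    truth_panel["y_mme_gt90"] = y_mme

    # --- prescription count, floor-censored at the prescriber count -------
    eta0 = eta_without_intercept("n_rx")
    mu = np.zeros(n_rows)
    if n_elig:
        scale = config.baseline_rates["n_rx"] * n_rows / np.exp(eta0[eligible]).sum()
        intercepts["n_rx"] = math.log(scale)
        mu[eligible] = scale * np.exp(eta0[eligible])
    alpha = config.dispersion
    r = 1.0 / alpha
    c = np.zeros(n_rows, dtype=int)
    if n_elig:
        c[eligible] = rng.negative_binomial(
            r, r / (r + mu[eligible]), size=n_elig
        )
    k = base["n_prescribers"].to_numpy()
    realized = np.where(eligible, np.maximum(c, k), 0)
    truth_panel["y_n_rx"] = c
    truth_panel["n_rx_realized"] = realized

    # --- materialize count + MME planting into the prescription table -----
    rx_aug = rx.reset_index(drop=True).copy()
    nonmat_panel = (rx_aug["is_mat"] == 0) & rx_aug["quarter"].isin(panel_q)
    groups = {
        key: list(lbls)
        for key, lbls in rx_aug.loc[nonmat_panel]
        .groupby(["patient_id", "quarter"])
        .groups.items()
    }
    drop_idx: list[int] = []
    clone_rows: list[pd.DataFrame] = []
    boost_idx: list[int] = []
    pids = base["patient_id"].to_numpy()
    qs = base["quarter"].to_numpy()
    for i in np.flatnonzero(eligible):
        idxs = groups.get((pids[i], qs[i]))
        if idxs is None:
            continue
        tgt = int(realized[i])
        sub = rx_aug.loc[idxs]
        first_per_presc = sub.drop_duplicates("prescriber_id").index.tolist()
        extras = [j for j in idxs if j not in set(first_per_presc)]
        kept = idxs
        if tgt < len(idxs):
            keep_extra = extras[: tgt - len(first_per_presc)]
            kept = first_per_presc + keep_extra
            drop_idx.extend(set(idxs) - set(kept))
        elif tgt > len(idxs):
            n_new = tgt - len(idxs)
            src = [idxs[j % len(idxs)] for j in range(n_new)]
            clones = rx_aug.loc[src].copy()
            clones["fill_day"] = rng.integers(0, 90, n_new)
            clone_rows.append(clones)
        if y_mme[i]:
            boost_idx.append(kept[0])

    if boost_idx:
        rx_aug.loc[boost_idx, ["drug_code", "daily_dose_mg", "mme_factor"]] = [
            "morphine", 150.0, 1.0,
        ]
    if drop_idx:
        rx_aug = rx_aug.drop(index=drop_idx)
    if clone_rows:
        rx_aug = pd.concat([rx_aug] + clone_rows, ignore_index=True)
    rx_aug = rx_aug.reset_index(drop=True)

    dx_aug = pd.concat([dx] + dx_new, ignore_index=True) if dx_new else dx.copy()

    truth = {
        "betas": betas,
        "intercepts": intercepts,
        "sigma_u": dict(config.sigma_u),
        "dispersion": config.dispersion,
        "control_effects": {k: dict(v) for k, v in config.control_effects.items()},
        "panel_quarters": panel_q,
        "panel": truth_panel,
    }
    return rx_aug, dx_aug, truth


def generate_study(config: SynthConfig, centrality_params: CentralityParams | None = None):
    """Run the full two-stage generation and the first network pass.

    Returns a dict with patients, prescribers, rx, dx (post-planting),
    the centrality table used for planting, and the truth record.
    """
    patients, prescribers = generate_population(config)
    rx0, dx0 = generate_claims(patients, prescribers, config)
    rx_f = filter_opioid_claims(rx0)
    cent = centrality_table(
        rx_f, config.panel_quarters, params=centrality_params,
        max_quarter=config.n_quarters - 1,
    )
    rx, dx, truth = plant_outcomes(patients, rx0, dx0, cent, config)
    return {
        "patients": patients,
        "prescribers": prescribers,
        "rx": rx,
        "dx": dx,
        "centrality": cent,
        "truth": truth,
        "config": config,
    }


def simulate_panel(
    n_patients: int = 2000,
    n_quarters: int = 4,
    family: str = "logit",
    baseline: float = 0.08,
    beta_bp: float = _log(1.5),
    beta_wp: float = _log(1.5),
    sigma_u: float = 1.0,
    dispersion: float = 0.8,
    within_sd: float = 15.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Directly simulated prominence panel for estimator calibration.

    Skips the claims/network machinery: percentile-like scores are drawn
    as a patient-level mean plus quarter noise (clipped to [0, 100]),
    and the outcome follows the planted GLMM exactly — no exposure
    censoring — which makes it the clean test bed for count-model
    recovery.  Columns: patient_id, quarter, pr_pct, y, bp, wp.
    """
    rng = np.random.default_rng(seed)
    pm = rng.uniform(0.0, 100.0, n_patients)
    x = np.clip(
        pm[:, None] + rng.normal(0.0, within_sd, (n_patients, n_quarters)), 0.0, 100.0
    )
    u = rng.normal(0.0, sigma_u, n_patients)
    df = pd.DataFrame(
        {
            "patient_id": np.repeat(np.arange(n_patients), n_quarters),
            "quarter": np.tile(np.arange(n_quarters), n_patients),
            "pr_pct": x.ravel(),
        }
    )
    df = decompose(df, column="pr_pct", scale=10.0)
    eta = (
        beta_bp * (df["bp"].to_numpy() - 5.0)
        + beta_wp * df["wp"].to_numpy()
        + u[df["patient_id"].to_numpy()]
    )
    if family == "logit":
        a = float(logit(baseline))
        df["y"] = (rng.random(len(df)) < expit(a + eta)).astype(int)
    elif family in ("poisson", "negbin"):
        mu = baseline * np.exp(eta)
        if family == "poisson":
            df["y"] = rng.poisson(mu)
        else:
            r = 1.0 / dispersion
            df["y"] = rng.negative_binomial(r, r / (r + mu))
        a = math.log(baseline)
    else:
        raise ValueError(f"unknown family {family!r}")
    df.attrs["truth"] = {
        "intercept": a, "beta_bp": beta_bp, "beta_wp": beta_wp,
        "sigma_u": sigma_u, "dispersion": dispersion, "family": family,
    }
    return df


# ---------------------------------------------------------------------------
# table round-trip
# ---------------------------------------------------------------------------

def write_tables(out_dir, patients, prescribers, rx, dx, truth=None) -> None:
    """Write the generated tables as delimited text (plus truth.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patients.to_csv(out / "patients.csv", index=False)
    prescribers.to_csv(out / "prescribers.csv", index=False)
    rx.to_csv(out / "prescriptions.csv", index=False)
    dx.to_csv(out / "diagnoses.csv", index=False)
    if truth is not None:
        scalars = {k: v for k, v in truth.items() if k != "panel"}
        (out / "truth.json").write_text(json.dumps(scalars, indent=2))
        truth["panel"].to_csv(out / "truth_panel.csv", index=False)


def read_tables(out_dir):
    """Read tables written by :func:`write_tables`."""
    out = Path(out_dir)
    kw = {"float_precision": "round_trip"}   # lossless float round-trip
    patients = pd.read_csv(out / "patients.csv", **kw)
    prescribers = pd.read_csv(out / "prescribers.csv", **kw)
    rx = pd.read_csv(out / "prescriptions.csv", **kw)
    dx = pd.read_csv(out / "diagnoses.csv", **kw)
    truth = None
    if (out / "truth.json").exists():
        truth = json.loads((out / "truth.json").read_text())
        if (out / "truth_panel.csv").exists():
            truth["panel"] = pd.read_csv(out / "truth_panel.csv")
    return patients, prescribers, rx, dx, truth
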