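"""Quarterly opioid-risk outcomes and analysis-panel assembly.

Four dependent variables per patient-quarter:

* ``n_rx`` — count of opioid fills (MAT excluded) across all prescribers.
* ``mme_gt90`` — whether the maximum daily morphine-milligram-equivalent
  dose over the quarter exceeds 90 mg, the CDC high-overdose-risk
  threshold.  Daily MME = daily dose × CDC conversion factor, summed over
  concurrently active prescriptions on a day grid.
* ``overdose_any`` — accidental poisoning by opioids or "unspecified"
  drugs (inclusive measure; the opioid-only variant is kept alongside).
* ``oud`` — opioid use disorder: ICD-10 abuse/dependence codes.

Controls: gender, age (per decade), insurance type, any cancer diagnosis
over the study period, and the number of unique opioid prescribers in
the quarter (so that network prominence is not just a prescriber count).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import filter_opioid_claims

__all__ = [
    "CodeDictionary",
    "count_rx",
    "count_prescribers",
    "max_daily_mme",
    "flag_codes",
    "assemble_panel",
    "restrict_high_risk",
]

QUARTER_DAYS = 90

#: states of the study region, reference category last
STATES = ["GA", "KY", "NC", "OH", "TN", "VA", "WV"]
INSURANCE_LEVELS = ["HMO", "POS", "Other"]


def _normalize(code: str) -> str:
    return str(code).replace(".", "").upper().strip()


@dataclass
class CodeDictionary:
    """ICD-10 code groups, stored as normalized (dot-free) prefixes.

    These lists are reconstructions from the clinical categories, not a
    published code set: accidental opioid poisoning T40.0x–T40.4x and
    T40.6x, unspecified-drug poisoning T50.9x (both requiring the
    accidental-intent 6th character '1'), opioid abuse/dependence
    F11.1x/F11.2x, and malignant neoplasms C00–C96.
    """

    overdose_opioid_prefixes: tuple = ("T400", "T401", "T402", "T403", "T404", "T406")
    overdose_unspecified_prefixes: tuple = ("T509",)
    oud_prefixes: tuple = ("F111", "F112")
    cancer_max_category: int = 96
    intent_position: int = 5          # index of the intent character in T-codes
    accidental_intent: str = "1"

    def _accidental(self, code: str) -> bool:
        return len(code) > self.intent_position and code[self.intent_position] == self.accidental_intent

    def is_overdose_opioid(self, code: str) -> bool:
        code = _normalize(code)
        return code.startswith(self.overdose_opioid_prefixes) and self._accidental(code)

    def is_overdose_unspecified(self, code: str) -> bool:
        code = _normalize(code)
        return code.startswith(self.overdose_unspecified_prefixes) and self._accidental(code)

    def is_oud(self, code: str) -> bool:
        return _normalize(code).startswith(self.oud_prefixes)

    def is_cancer(self, code: str) -> bool:
        code = _normalize(code)
        if len(code) < 3 or code[0] != "C" or not code[1:3].isdigit():
            return False
        return int(code[1:3]) <= self.cancer_max_category


def count_rx(rx_filtered: pd.DataFrame, patient_id, quarter: int) -> int:
    """Number of opioid fills for one patient in one quarter (not pooled)."""
    m = (rx_filtered["patient_id"] == patient_id) & (rx_filtered["quarter"] == quarter)
    return int(m.sum())


def count_prescribers(rx_filtered: pd.DataFrame, patient_id, quarter: int) -> int:
    """Distinct opioid prescribers for one patient in one quarter."""
    m = (rx_filtered["patient_id"] == patient_id) & (rx_filtered["quarter"] == quarter)
    return int(rx_filtered.loc[m, "prescriber_id"].nunique())


def _max_daily_from_arrays(fill_day, days_supply, daily_mme, quarter_days=QUARTER_DAYS):
    """Max over the quarter's day grid of the summed MME of active fills."""
    grid = np.zeros(quarter_days)
    for d0, ds, mme in zip(fill_day, days_supply, daily_mme):
        lo = int(max(d0, 0))
        hi = int(min(d0 + ds, quarter_days))
        if hi > lo:
            grid[lo:hi] += mme
    return float(grid.max()) if quarter_days else 0.0


def max_daily_mme(
    rx: pd.DataFrame, patient_id, quarter: int, quarter_days: int = QUARTER_DAYS
) -> tuple[float, int]:
    """Maximum daily MME over a quarter and the >90 mg flag (strict).

    Each fill contributes daily_dose_mg × mme_factor on every day it is
    active (fill_day .. fill_day + days_supply, clipped to the quarter);
    concurrent fills are summed per day and the quarter maximum taken.
    MAT fills are excluded.  Flag is 1 iff the maximum exceeds 90 mg
    strictly (90.0 exactly does not flag).
    """
    sub = rx.loc[
        (rx["patient_id"] == patient_id)
        & (rx["quarter"] == quarter)
        & (rx["is_mat"] == 0)
    ]
    if len(sub) == 0:
        return 0.0, 0
    if (sub["daily_dose_mg"] <= 0).any() or (sub["mme_factor"] <= 0).any():
        raise ValueError(
            f"nonpositive dose or MME factor for patient {patient_id!r} quarter {quarter}"
        )
    mme = sub["daily_dose_mg"].to_numpy() * sub["mme_factor"].to_numpy()
    day = sub["fill_day"].to_numpy() if "fill_day" in sub.columns else np.zeros(len(sub))
    supply = (
        sub["days_supply"].to_numpy()
        if "days_supply" in sub.columns
        else np.full(len(sub), quarter_days)
    )
    mx = _max_daily_from_arrays(day, supply, mme, quarter_days)
    return mx, int(mx > 90.0)


def flag_codes(
    dx: pd.DataFrame,
    patient_id,
    quarter: int,
    codes: CodeDictionary | None = None,
    which: str = "overdose_inclusive",
) -> int:
    """1 iff the patient has a matching ICD-10 code in the quarter.

    ``which`` is one of 'overdose_inclusive' (opioid or unspecified-drug
    accidental poisoning), 'overdose_opioid_only', or 'oud'.
    """
    codes = codes or CodeDictionary()
    preds = {
        "overdose_inclusive": lambda c: codes.is_overdose_opioid(c)
        or codes.is_overdose_unspecified(c),
        "overdose_opioid_only": codes.is_overdose_opioid,
        "oud": codes.is_oud,
    }
    if which not in preds:
        raise ValueError(f"unknown outcome {which!r}; expected one of {sorted(preds)}")
    sub = dx.loc[(dx["patient_id"] == patient_id) & (dx["quarter"] == quarter)]
    return int(any(preds[which](c) for c in sub["icd10_code"]))


def _mme_by_group(rx_f: pd.DataFrame, quarter_days: int) -> pd.DataFrame:
    if len(rx_f) == 0:
        return pd.DataFrame(columns=["patient_id", "quarter", "max_daily_mme"])
    if (rx_f["daily_dose_mg"] <= 0).any() or (rx_f["mme_factor"] <= 0).any():
        bad = rx_f.index[(rx_f["daily_dose_mg"] <= 0) | (rx_f["mme_factor"] <= 0)][:5]
        raise ValueError(f"nonpositive dose/MME factor at rows {list(bad)}")
    tmp = rx_f.assign(
        _mme=rx_f["daily_dose_mg"] * rx_f["mme_factor"],
        _day=rx_f["fill_day"] if "fill_day" in rx_f.columns else 0,
        _supply=rx_f["days_supply"] if "days_supply" in rx_f.columns else quarter_days,
    )
    out = (
        tmp.groupby(["patient_id", "quarter"])
        .apply(
            lambda g: _max_daily_from_arrays(
                g["_day"].to_numpy(), g["_supply"].to_numpy(), g["_mme"].to_numpy(),
                quarter_days,
            ),
            include_groups=False,
        )
        .rename("max_daily_mme")
        .reset_index()
    )
    return out


def assemble_panel(
    patients: pd.DataFrame,
    rx: pd.DataFrame,
    dx: pd.DataFrame,
    centrality: pd.DataFrame,
    panel_quarters,
    codes: CodeDictionary | None = None,
    quarter_days: int = QUARTER_DAYS,
) -> pd.DataFrame:
    """One row per included patient per panel quarter.

    Inclusion: patients with at least one non-MAT opioid fill anywhere in
    the study window; an included patient contributes a row for *every*
    panel quarter (zeros where inactive).  Cancer is a study-period-level
    flag, constant within patient.  Prominence columns are joined from
    the centrality table, which must cover every panel quarter.
    """
    codes = codes or CodeDictionary()
    panel_quarters = list(panel_quarters)
    have_q = set(centrality["quarter"].unique())
    missing = [q for q in panel_quarters if q not in have_q]
    if missing:
        raise ValueError(
            f"centrality table lacks panel quarters {missing}; compute centrality first"
        )

    rx_f = filter_opioid_claims(rx)
    included = sorted(rx_f["patient_id"].unique())
    base = pd.MultiIndex.from_product(
        [included, panel_quarters], names=["patient_id", "quarter"]
    ).to_frame(index=False)

    rx_q = rx_f.loc[rx_f["quarter"].isin(panel_quarters)]
    grp = rx_q.groupby(["patient_id", "quarter"])
    counts = grp.size().rename("n_rx").reset_index()
    nprs = grp["prescriber_id"].nunique().rename("n_prescribers").reset_index()
    mme = _mme_by_group(rx_q, quarter_days)

    panel = (
        base.merge(counts, how="left", on=["patient_id", "quarter"])
        .merge(nprs, how="left", on=["patient_id", "quarter"])
        .merge(mme, how="left", on=["patient_id", "quarter"])
    )
    panel[["n_rx", "n_prescribers"]] = (
        panel[["n_rx", "n_prescribers"]].fillna(0).astype(int)
    )
    panel["max_daily_mme"] = panel["max_daily_mme"].fillna(0.0)
    panel["mme_gt90"] = (panel["max_daily_mme"] > 90.0).astype(int)

    # diagnosis flags, vectorized over the dx table
    dxx = dx.copy()
    dxx["_norm"] = dxx["icd10_code"].map(_normalize)
    dxx["_od_op"] = dxx["_norm"].map(codes.is_overdose_opioid)
    dxx["_od_un"] = dxx["_norm"].map(codes.is_overdose_unspecified)
    dxx["_oud"] = dxx["_norm"].map(codes.is_oud)
    dxx["_cancer"] = dxx["_norm"].map(codes.is_cancer)
    flags = (
        dxx.groupby(["patient_id", "quarter"])[["_od_op", "_od_un", "_oud"]]
        .any()
        .reset_index()
    )
    panel = panel.merge(flags, how="left", on=["patient_id", "quarter"])
    for c in ("_od_op", "_od_un", "_oud"):
        panel[c] = panel[c].notna() & panel[c].eq(True)
    panel["overdose_opioid_only"] = panel["_od_op"].astype(int)
    panel["overdose_any"] = (panel["_od_op"] | panel["_od_un"]).astype(int)
    panel["oud"] = panel["_oud"].astype(int)
    panel = panel.drop(columns=["_od_op", "_od_un", "_oud"])

    cancer_pat = set(dxx.loc[dxx["_cancer"], "patient_id"].unique())
    panel["cancer_dx"] = panel["patient_id"].isin(cancer_pat).astype(int)

    demo = patients.set_index("patient_id")
    panel["female"] = demo["female"].reindex(panel["patient_id"]).to_numpy().astype(int)
    panel["age_10yr"] = demo["age_years"].reindex(panel["patient_id"]).to_numpy() / 10.0
    panel["state"] = demo["state"].reindex(panel["patient_id"]).to_numpy()
    ins = demo["insurance"].reindex(panel["patient_id"]).to_numpy()
    panel["insurance"] = ins
    for lvl in INSURANCE_LEVELS[:-1]:                # 'Other' is the reference
        panel[f"ins_{lvl}"] = (ins == lvl).astype(int)
    for st in STATES[:-1]:                           # 'WV' is the reference
        panel[f"state_{st}"] = (panel["state"] == st).astype(int)

    cent_cols = [
        c for c in ("pr_raw", "pr_pct", "pr_std", "degree", "degree_log", "bip_pr_pct")
        if c in centrality.columns
    ]
    panel = panel.merge(
        centrality[["patient_id", "quarter"] + cent_cols],
        how="left",
        on=["patient_id", "quarter"],
    )
    return panel


def restrict_high_risk(panel: pd.DataFrame) -> pd.DataFrame:
    """Keep patients whose prescriber count reaches 2 in at least one quarter.

    The restriction is patient-level: a qualifying patient keeps all their
    quarters, others are dropped entirely.  This removes patients who are
    clearly not doctor shopping (never more than one opioid prescriber)
    and probes whether prominence separates moderate from high risk.
    """
    keep = panel.groupby("patient_id")["n_prescribers"].transform("max") >= 2
    return panel.loc[keep].copy()
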