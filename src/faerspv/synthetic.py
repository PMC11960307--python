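"""Seeded generator of FAERS-shaped quarterly extracts with planted signals.

The generator emits the five quarterly ASCII tables (DEMO, DRUG, REAC, THER,
OUTC) in the ``$``-delimited dialect, together with a machine-readable ground
truth: which report version survives deduplication, which cases name the
target drug, and the analytically expected 2×2 cell counts for every planted
drug–event signal.

Sampling model
--------------
Each case names exactly one primary-suspect (PS) drug — the target drug with
probability ``target_fraction``, otherwise a background drug — plus a few
concomitants. Reaction PTs are drawn i.i.d. from a skewed baseline
distribution; for target-drug cases the probability of each planted PT is
multiplied by its relative risk and the vector renormalised, so the expected
2×2 table of every planted pair is known in closed form. Everything else
(demographics, reporters, countries, outcomes, onset times) is sampled
independently from configurable categorical distributions whose defaults
mirror a real calcimimetic safety profile: mostly elderly dialysis patients,
physician reporters, US/Japan reporting, and a right-skewed onset-time
distribution with a median of 82 days.

A single master seed drives everything; per-quarter child seeds are derived
by fixed offsets so that adding quarters never perturbs earlier ones.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from faerspv._util import AGE_BANDS

__all__ = [
    "SOC_VOCABULARY",
    "GeneratorConfig",
    "GroundTruth",
    "PlantedSignal",
    "generate_quarters",
    "mark_retained",
    "plant_duplicates",
]

#: The 26 System Organ Classes used by the synthetic MedDRA dictionary
#: (name, SOC code). PT ``PT_k`` is assigned SOC ``k mod 26``.
SOC_VOCABULARY: tuple[tuple[str, str], ...] = (
    ("Injury, poisoning and procedural complications", "10022117"),
    ("Gastrointestinal disorders", "10017947"),
    ("General disorders and administration site conditions", "10018065"),
    ("Investigations", "10022891"),
    ("Infections and infestations", "10021881"),
    ("Nervous system disorders", "10029205"),
    ("Cardiac disorders", "10007541"),
    ("Musculoskeletal and connective tissue disorders", "10028395"),
    ("Metabolism and nutrition disorders", "10027433"),
    ("Skin and subcutaneous tissue disorders", "10040785"),
    ("Vascular disorders", "10047065"),
    ("Respiratory, thoracic and mediastinal disorders", "10038738"),
    ("Neoplasms benign, malignant and unspecified (incl cysts and polyps)", "10029104"),
    ("Psychiatric disorders", "10037175"),
    ("Hepatobiliary disorders", "10019805"),
    ("Surgical and medical procedures", "10042613"),
    ("Eye disorders", "10015919"),
    ("Blood and lymphatic system disorders", "10005329"),
    ("Product issues", "10077536"),
    ("Immune system disorders", "10021428"),
    ("Renal and urinary disorders", "10038359"),
    ("Endocrine disorders", "10014698"),
    ("Ear and labyrinth disorders", "10013993"),
    ("Reproductive system and breast disorders", "10038604"),
    ("Social circumstances", "10041244"),
    ("Congenital, familial and genetic disorders", "10010331"),
)

_SEXES = ("M", "F")
_AGE_CODS = ("YR", "MON", "DEC")
_AGE_COD_PROBS = (0.90, 0.05, 0.05)
_AGE_RANGES = {"<18": (1.0, 17.9), "18-44": (18.0, 44.9), "45-64": (45.0, 64.9), ">=65": (65.0, 90.0)}
_OUTCOME_CODES = ("DE", "HO", "LT", "DS", "CA", "RI", "OT")


@dataclass(frozen=True)
class PlantedSignal:
    """A drug–event association planted into the generated data.

    ``rr`` multiplies the baseline probability of ``pt`` among the reactions
    of target-drug reports (after which the PT distribution is renormalised).
    Optional ``sex`` / ``age_band`` restrict the excess risk to one stratum,
    which is how sex- or age-specific signals are emulated.
    """

    pt: str
    rr: float
    sex: str | None = None
    age_band: str | None = None


def _as_signal(item) -> PlantedSignal:
    if isinstance(item, PlantedSignal):
        return item
    return PlantedSignal(*item)


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic FAERS extract."""

    n_cases: int = 2000
    n_background_drugs: int = 40
    n_pts: int = 100
    target_drug_names: tuple[str, ...] = ("ETELCALCETIDE", "PARSABIV", "AMG 416")
    target_prod_ai: str = "ETELCALCETIDE"
    planted_signals: tuple = ()
    target_fraction: float = 0.10
    duplicate_rate: float = 0.10
    name_variant_probs: tuple[float, ...] = (0.50, 0.35, 0.15)
    missing_sex_rate: float = 0.26
    missing_age_rate: float = 0.45
    missing_date_rate: float = 0.10
    sex_probs: Mapping[str, float] = field(default_factory=lambda: {"M": 0.542, "F": 0.458})
    age_band_probs: Mapping[str, float] = field(
        default_factory=lambda: {"<18": 0.02, "18-44": 0.09, "45-64": 0.37, ">=65": 0.52}
    )
    reporter_probs: Mapping[str, float] = field(
        default_factory=lambda: {"MD": 0.52, "HP": 0.26, "PH": 0.10, "CN": 0.06, "OT": 0.06}
    )
    country_probs: Mapping[str, float] = field(
        default_factory=lambda: {"US": 0.64, "JP": 0.31, "DE": 0.02, "FR": 0.02, "CA": 0.01}
    )
    outcome_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "OT": 0.40,
            "NONE": 0.13,
            "HO": 0.29,
            "DE": 0.12,
            "LT": 0.02,
            "DS": 0.02,
            "RI": 0.02,
        }
    )
    mean_events_per_case: float = 2.2
    tto_distribution: tuple[str, Mapping[str, float]] = (
        "lognormal",
        None,  # filled in __post_init__ with {"median_days": 82.0, "sigma": 1.2}
    )
    quarters: tuple[str, ...] = ("2023q1", "2023q2")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tto_distribution[1] is None:
            self.tto_distribution = ("lognormal", {"median_days": 82.0, "sigma": 1.2})

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        def _positive_int(name, v):
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValueError(f"GeneratorConfig.{name} must be a positive integer, got {v!r}")

        _positive_int("n_cases", self.n_cases)
        _positive_int("n_background_drugs", self.n_background_drugs)
        _positive_int("n_pts", self.n_pts)
        for name in ("duplicate_rate", "missing_sex_rate", "missing_age_rate", "missing_date_rate", "target_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"GeneratorConfig.{name} must lie in [0, 1], got {v!r}")
        if self.duplicate_rate >= 1.0:
            raise ValueError("GeneratorConfig.duplicate_rate must lie in [0, 1)")
        if not self.target_drug_names:
            raise ValueError("GeneratorConfig.target_drug_names must be non-empty")
        if len(self.name_variant_probs) != len(self.target_drug_names):
            raise ValueError(
                "GeneratorConfig.name_variant_probs must have one probability per target_drug_names entry"
            )
        for name in ("name_variant_probs",):
            if abs(sum(self.name_variant_probs) - 1.0) > 1e-9:
                raise ValueError(f"GeneratorConfig.{name} must sum to 1")
        for name in ("sex_probs", "age_band_probs", "reporter_probs", "country_probs", "outcome_probs"):
            probs = dict(getattr(self, name))
            if any(p < 0 or p > 1 for p in probs.values()):
                raise ValueError(f"GeneratorConfig.{name} has probabilities outside [0, 1]")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"GeneratorConfig.{name} must sum to 1 within 1e-9")
        if set(self.age_band_probs) != set(AGE_BANDS):
            raise ValueError(f"GeneratorConfig.age_band_probs must cover bands {AGE_BANDS}")
        if self.mean_events_per_case < 1.0:
            raise ValueError("GeneratorConfig.mean_events_per_case must be >= 1")
        family, params = self.tto_distribution
        if family != "lognormal":
            raise ValueError(f"GeneratorConfig.tto_distribution family {family!r} not supported")
        if params.get("median_days", 0) <= 0 or params.get("sigma", 0) <= 0:
            raise ValueError("GeneratorConfig.tto_distribution requires positive median_days and sigma")
        if not self.quarters:
            raise ValueError("GeneratorConfig.quarters must be non-empty")
        for q in self.quarters:
            _parse_quarter(q)
        vocab = set(self.pt_names())
        for raw in self.planted_signals:
            sig = _as_signal(raw)
            if sig.rr <= 0:
                raise ValueError(f"GeneratorConfig.planted_signals: relative risk for {sig.pt!r} must be > 0")
            if sig.pt not in vocab:
                raise ValueError(
                    f"GeneratorConfig.planted_signals: PT {sig.pt!r} is not in the generated vocabulary"
                )
            if sig.sex is not None and sig.sex not in _SEXES:
                raise ValueError(f"GeneratorConfig.planted_signals: sex restriction {sig.sex!r} invalid")
            if sig.age_band is not None and sig.age_band not in AGE_BANDS:
                raise ValueError(f"GeneratorConfig.planted_signals: age_band restriction {sig.age_band!r} invalid")

    # -- derived vocabulary ---------------------------------------------
    def pt_names(self) -> list[str]:
        return [f"PT_{k:04d}" for k in range(1, self.n_pts + 1)]

    def pt_soc(self) -> dict[str, tuple[str, str]]:
        names = self.pt_names()
        return {pt: SOC_VOCABULARY[k % len(SOC_VOCABULARY)] for k, pt in enumerate(names)}

    def baseline_pt_probs(self) -> np.ndarray:
        """Skewed baseline PT distribution (a few common terms, a long tail)."""
        w = 1.0 / (np.arange(self.n_pts) + 10.0)
        return w / w.sum()

    def signals(self) -> list[PlantedSignal]:
        return [_as_signal(s) for s in self.planted_signals]


@dataclass
class GroundTruth:
    """What the generator actually planted, for use as a test oracle."""

    retained: dict[int, int]  # caseid -> surviving primaryid
    versions: dict[int, list[int]]  # caseid -> all emitted primaryids
    target_caseids: list[int]
    signals: list[dict]  # per planted signal: pt, rr, strata, expected_a, ...
    pt_soc: dict[str, tuple[str, str]]
    expected_target_events: float
    expected_total_events: float
    n_cases: int
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "retained": {str(k): v for k, v in self.retained.items()},
            "versions": {str(k): v for k, v in self.versions.items()},
            "target_caseids": list(self.target_caseids),
            "signals": self.signals,
            "pt_soc": {pt: list(sc) for pt, sc in self.pt_soc.items()},
            "expected_target_events": self.expected_target_events,
            "expected_total_events": self.expected_total_events,
            "n_cases": self.n_cases,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            retained={int(k): v for k, v in d["retained"].items()},
            versions={int(k): v for k, v in d["versions"].items()},
            target_caseids=list(d["target_caseids"]),
            signals=d["signals"],
            pt_soc={pt: tuple(sc) for pt, sc in d["pt_soc"].items()},
            expected_target_events=d["expected_target_events"],
            expected_total_events=d["expected_total_events"],
            n_cases=d["n_cases"],
            seed=d["seed"],
        )


# ---------------------------------------------------------------------------
# duplicate planting


def mark_retained(versions: pd.DataFrame) -> pd.Series:
    """Boolean mask of the version kept by the FDA deduplication rule.

    Per CASEID keep the row with the highest FDA_DT; among ties on
    (CASEID, FDA_DT), the highest PRIMARYID.
    """
    order = versions.sort_values(["caseid", "fda_dt", "primaryid"], kind="mergesort")
    keep_idx = order.groupby("caseid", sort=False).tail(1).index
    mask = pd.Series(False, index=versions.index)
    mask.loc[keep_idx] = True
    return mask


def plant_duplicates(case_versions: pd.DataFrame, duplicate_rate: float, seed) -> pd.DataFrame:
    """Expand a one-row-per-case frame with duplicate report versions.

    A ``duplicate_rate`` fraction of CASEIDs receives one or two extra
    versions with fresh PRIMARYIDs (derived as ``primaryid*10 + caseversion``)
    and FDA_DT values shifted by a few weeks either way (about a third of the
    shifts are zero, producing exact FDA_DT ties that only the PRIMARYID
    tie-break can resolve). The returned frame carries a ``retained`` column
    marking the version the FDA rule keeps.
    """
    if not 0.0 <= duplicate_rate < 1.0:
        raise ValueError("duplicate_rate must lie in [0, 1)")
    df = case_versions.copy()
    if "caseversion" not in df.columns:
        df["caseversion"] = 1
    rng = np.random.default_rng(seed)
    n = len(df)
    dup_mask = rng.random(n) < duplicate_rate
    extras = []
    if dup_mask.any():
        base = df.loc[dup_mask]
        n_extra = rng.integers(1, 3, size=len(base))  # 1 or 2 extra versions
        fda = pd.to_datetime(base["fda_dt"].astype(int), format="%Y%m%d")
        for v in (2, 3):
            sel = n_extra >= (v - 1)
            rows = base.loc[sel].copy()
            offs = rng.integers(-20, 61, size=len(rows))
            offs[rng.random(len(rows)) < 0.35] = 0
            new_fda = fda[sel] + pd.to_timedelta(offs, unit="D")
            rows["fda_dt"] = (
                new_fda.dt.year * 10000 + new_fda.dt.month * 100 + new_fda.dt.day
            ).astype(np.int64)
            rows["primaryid"] = rows["primaryid"].astype(np.int64) * 10 + v
            rows["caseversion"] = v
            extras.append(rows)
    out = pd.concat([df, *extras], ignore_index=True) if extras else df.reset_index(drop=True)
    out = out.sort_values(["caseid", "caseversion"], kind="mergesort").reset_index(drop=True)
    out["retained"] = mark_retained(out)
    return out


# ---------------------------------------------------------------------------
# expected counts for planted signals


def _stratum_probs(cfg: GeneratorConfig) -> dict[tuple[str, str], float]:
    """Joint probability of each (sex, age_band) stratum, UNK included."""
    sex_p = {"UNK": cfg.missing_sex_rate}
    for s, p in cfg.sex_probs.items():
        sex_p[s] = (1.0 - cfg.missing_sex_rate) * p
    band_p = {"UNK": cfg.missing_age_rate}
    for b, p in cfg.age_band_probs.items():
        band_p[b] = (1.0 - cfg.missing_age_rate) * p
    return {(s, b): ps * pb for s, ps in sex_p.items() for b, pb in band_p.items()}


def _pt_probs_for_stratum(cfg: GeneratorConfig, sex: str, band: str) -> np.ndarray:
    """Target-case PT distribution in one stratum: plant RRs, renormalise."""
    base = cfg.baseline_pt_probs()
    idx = {pt: k for k, pt in enumerate(cfg.pt_names())}
    w = base.copy()
    for sig in cfg.signals():
        if sig.sex is not None and sig.sex != sex:
            continue
        if sig.age_band is not None and sig.age_band != band:
            continue
        w[idx[sig.pt]] *= sig.rr
    return w / w.sum()


def _expected_distinct_hits(p: float, mu: float) -> float:
    """P(a case reports the PT at least once) with 1+Poisson(mu-1) draws.

    Reaction draws are i.i.d. with probability p and duplicate (case, PT)
    pairs collapse, so the expected distinct count per case is
    1 - (1-p)·exp(-(mu-1)·p), not mu·p.
    """
    return 1.0 - (1.0 - p) * math.exp(-(mu - 1.0) * p)


def _expected_signal_stats(cfg: GeneratorConfig) -> list[dict]:
    base = cfg.baseline_pt_probs()
    idx = {pt: k for k, pt in enumerate(cfg.pt_names())}
    strata = _stratum_probs(cfg)
    n_target = cfg.n_cases * cfg.target_fraction
    mu = cfg.mean_events_per_case
    out = []
    for sig in cfg.signals():
        k = idx[sig.pt]
        p_eff = sum(p_st * _pt_probs_for_stratum(cfg, s, b)[k] for (s, b), p_st in strata.items())
        expected_a = n_target * sum(
            p_st * _expected_distinct_hits(_pt_probs_for_stratum(cfg, s, b)[k], mu)
            for (s, b), p_st in strata.items()
        )
        expected_a_independence = n_target * _expected_distinct_hits(float(base[k]), mu)
        out.append(
            {
                "pt": sig.pt,
                "rr": sig.rr,
                "sex": sig.sex,
                "age_band": sig.age_band,
                "baseline_pt_prob": float(base[k]),
                "effective_pt_prob": float(p_eff),
                "expected_a": float(expected_a),
                "expected_a_independence": float(expected_a_independence),
            }
        )
    return out


# ---------------------------------------------------------------------------
# quarter generation


def _parse_quarter(label: str) -> tuple[int, int]:
    try:
        year, q = label.lower().split("q")
        year_i, q_i = int(year), int(q)
    except Exception as exc:  # noqa: BLE001 - re-raised with the offending value
        raise ValueError(f"quarter label {label!r} is not of the form YYYYqN") from exc
    if not 1 <= q_i <= 4:
        raise ValueError(f"quarter label {label!r} is not of the form YYYYqN")
    return year_i, q_i


def _quarter_start(label: str) -> _dt.date:
    year, q = _parse_quarter(label)
    return _dt.date(year, 3 * (q - 1) + 1, 1)


def _dates_to_int(dates: pd.Series) -> np.ndarray:
    return (dates.dt.year * 10000 + dates.dt.month * 100 + dates.dt.day).to_numpy(np.int64)


def _partialise(date_int: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Blank the day component (YYYYMM00) where mask is set."""
    out = date_int.copy()
    out[mask] = (out[mask] // 100) * 100
    return out


def _categorical(rng: np.random.Generator, probs: Mapping[str, float], size: int) -> np.ndarray:
    keys = np.array(list(probs.keys()), dtype=object)
    p = np.array(list(probs.values()), dtype=float)
    return keys[rng.choice(len(keys), size=size, p=p / p.sum())]


def _generate_one_quarter(cfg: GeneratorConfig, qi: int, n_q: int, id_base: int):
    rng = np.random.default_rng([cfg.seed, qi])
    label = cfg.quarters[qi]
    qstart = _quarter_start(label)
    pt_names = np.array(cfg.pt_names(), dtype=object)

    caseid = id_base + np.arange(n_q, dtype=np.int64)
    primaryid = caseid * 10 + 1
    is_target = rng.random(n_q) < cfg.target_fraction

    # demographics
    sex = np.where(
        rng.random(n_q) < cfg.missing_sex_rate, "", _categorical(rng, cfg.sex_probs, n_q)
    ).astype(object)
    band = np.where(
        rng.random(n_q) < cfg.missing_age_rate, "UNK", _categorical(rng, cfg.age_band_probs, n_q)
    ).astype(object)
    age_years = np.full(n_q, np.nan)
    for b, (lo, hi) in _AGE_RANGES.items():
        m = band == b
        age_years[m] = rng.uniform(lo, hi, m.sum())
    age_cod = _categorical(rng, dict(zip(_AGE_CODS, _AGE_COD_PROBS)), n_q)
    age_val = np.empty(n_q, dtype=object)
    for i in range(n_q):
        if band[i] == "UNK":
            age_val[i], age_cod[i] = "", ""
        elif age_cod[i] == "YR":
            age_val[i] = str(int(round(age_years[i])))
        elif age_cod[i] == "MON":
            age_val[i] = str(int(round(age_years[i] * 12)))
        else:  # DEC
            age_val[i] = f"{age_years[i] / 10.0:.1f}"

    occp = _categorical(rng, cfg.reporter_probs, n_q)
    country = _categorical(rng, cfg.country_probs, n_q)
    outcome = _categorical(rng, cfg.outcome_probs, n_q)

    # dates: therapy start -> event (start + TTO) -> FDA receipt
    fda = pd.to_datetime(qstart) + pd.to_timedelta(rng.integers(0, 90, n_q), unit="D")
    report_lag = rng.integers(0, 31, n_q)
    family, params = cfg.tto_distribution
    tto = np.round(
        rng.lognormal(math.log(params["median_days"]), params["sigma"], n_q)
    ).astype(np.int64)
    event = fda - pd.to_timedelta(report_lag, unit="D")
    start = event - pd.to_timedelta(tto, unit="D")
    fda_int = _dates_to_int(pd.Series(fda))
    event_int = _partialise(_dates_to_int(pd.Series(event)), rng.random(n_q) < cfg.missing_date_rate)
    start_int = _partialise(_dates_to_int(pd.Series(start)), rng.random(n_q) < cfg.missing_date_rate)

    demo = pd.DataFrame(
        {
            "primaryid": primaryid,
            "caseid": caseid,
            "caseversion": 1,
            "fda_dt": fda_int,
            "event_dt": event_int,
            "sex": sex,
            "age": age_val,
            "age_cod": age_cod,
            "occp_cod": occp,
            "occr_country": country,
        }
    )

    # reactions: 1 + Poisson(mean - 1) draws per case, distinct PTs kept
    n_events = 1 + rng.poisson(cfg.mean_events_per_case - 1.0, n_q)
    case_rep = np.repeat(np.arange(n_q), n_events)
    pt_idx = np.empty(case_rep.size, dtype=np.int64)
    bg_events = ~is_target[case_rep]
    base_p = cfg.baseline_pt_probs()
    pt_idx[bg_events] = rng.choice(cfg.n_pts, size=int(bg_events.sum()), p=base_p)
    # target events: PT distribution depends on the (sex, band) stratum
    tgt_events = ~bg_events
    if tgt_events.any():
        ev_sex = np.where(sex[case_rep] == "", "UNK", sex[case_rep])
        ev_band = band[case_rep]
        keys = pd.Series(list(zip(ev_sex, ev_band)))
        for key in sorted(set(keys[tgt_events])):
            m = tgt_events & (keys == key).to_numpy()
            p = _pt_probs_for_stratum(cfg, *key)
            pt_idx[m] = rng.choice(cfg.n_pts, size=int(m.sum()), p=p)
    reac = pd.DataFrame(
        {
            "primaryid": primaryid[case_rep],
            "caseid": caseid[case_rep],
            "pt": pt_names[pt_idx],
        }
    ).drop_duplicates(["caseid", "pt"])

    # drugs: one PS drug per case plus 0-2 concomitants
    variant = rng.choice(len(cfg.target_drug_names), size=n_q, p=np.asarray(cfg.name_variant_probs))
    bg_name_idx = rng.integers(0, cfg.n_background_drugs, n_q)
    ps_name = np.where(
        is_target,
        np.array(cfg.target_drug_names, dtype=object)[variant],
        np.array([f"BGDRUG{k:03d}" for k in range(cfg.n_background_drugs)], dtype=object)[bg_name_idx],
    )
    has_ai = rng.random(n_q) < 0.7
    ps_ai = np.where(
        is_target,
        np.where(has_ai, cfg.target_prod_ai, ""),
        np.where(has_ai, np.char.add("BGACTIVE", np.char.zfill(bg_name_idx.astype(str), 3)).astype(object), ""),
    )
    drug_frames = [
        pd.DataFrame(
            {
                "primaryid": primaryid,
                "caseid": caseid,
                "drug_seq": 1,
                "role_cod": "PS",
                "drugname": ps_name,
                "prod_ai": ps_ai,
            }
        )
    ]
    n_con = rng.integers(0, 3, n_q)
    for seq in (2, 3):
        m = n_con >= (seq - 1)
        if m.any():
            con_idx = rng.integers(0, cfg.n_background_drugs, int(m.sum()))
            drug_frames.append(
                pd.DataFrame(
                    {
                        "primaryid": primaryid[m],
                        "caseid": caseid[m],
                        "drug_seq": seq,
                        "role_cod": "C",
                        "drugname": [f"BGDRUG{k:03d}" for k in con_idx],
                        "prod_ai": [f"BGACTIVE{k:03d}" for k in con_idx],
                    }
                )
            )
    drug = pd.concat(drug_frames, ignore_index=True)

    ther = pd.DataFrame(
        {
            "primaryid": primaryid,
            "caseid": caseid,
            "dsg_drug_seq": 1,
            "start_dt": start_int,
        }
    )
    has_outcome = outcome != "NONE"
    outc = pd.DataFrame(
        {
            "primaryid": primaryid[has_outcome],
            "caseid": caseid[has_outcome],
            "outc_cod": outcome[has_outcome],
        }
    )

    # duplicate report versions
    expanded = plant_duplicates(
        demo[["caseid", "primaryid", "caseversion", "fda_dt"]],
        cfg.duplicate_rate,
        [cfg.seed, 10_000 + qi],
    )
    extra = expanded[expanded["caseversion"] > 1]
    if len(extra):
        rest = demo.drop(columns=["primaryid", "caseversion", "fda_dt"]).set_index("caseid")
        extra_demo = extra.drop(columns=["retained"]).join(rest, on="caseid")
        demo_full = pd.concat([demo, extra_demo[demo.columns]], ignore_index=True)
        child_extra = []
        for tbl in (drug, reac, ther, outc):
            ce = tbl.drop(columns=["primaryid"]).merge(
                extra[["caseid", "primaryid"]], on="caseid", how="inner"
            )
            child_extra.append(ce[tbl.columns])
        drug = pd.concat([drug, child_extra[0]], ignore_index=True)
        reac = pd.concat([reac, child_extra[1]], ignore_index=True)
        ther = pd.concat([ther, child_extra[2]], ignore_index=True)
        outc = pd.concat([outc, child_extra[3]], ignore_index=True)
    else:
        demo_full = demo

    retained = dict(
        zip(
            expanded.loc[expanded["retained"], "caseid"].astype(int),
            expanded.loc[expanded["retained"], "primaryid"].astype(int),
        )
    )
    versions = {
        int(cid): sorted(int(p) for p in grp)
        for cid, grp in expanded.groupby("caseid")["primaryid"]
    }
    tables = {
        "demo": demo_full.sort_values("primaryid", kind="mergesort"),
        "drug": drug.sort_values(["primaryid", "drug_seq"], kind="mergesort"),
        "reac": reac.sort_values(["primaryid", "pt"], kind="mergesort"),
        "ther": ther.sort_values(["primaryid", "dsg_drug_seq"], kind="mergesort"),
        "outc": outc.sort_values(["primaryid", "outc_cod"], kind="mergesort"),
    }
    return tables, retained, versions, caseid[is_target].astype(int).tolist()


def generate_quarters(config: GeneratorConfig, out_dir: str | Path) -> GroundTruth:
    """Write one subdirectory of ``$``-delimited tables per quarter.

    Returns the :class:`GroundTruth` (also written alongside the data as
    ``ground_truth.json``), plus a ``synthetic_meddra.txt`` dictionary file
    mapping the generated PT vocabulary to its 26 SOCs.
    """
    config.validate()
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc

    n_quarters = len(config.quarters)
    base_n = config.n_cases // n_quarters
    counts = [base_n + (1 if i < config.n_cases % n_quarters else 0) for i in range(n_quarters)]

    retained: dict[int, int] = {}
    versions: dict[int, list[int]] = {}
    target_caseids: list[int] = []
    for qi, label in enumerate(config.quarters):
        tables, ret_q, ver_q, tgt_q = _generate_one_quarter(
            config, qi, counts[qi], id_base=(qi + 1) * 10_000_000
        )
        qdir = out / label
        qdir.mkdir(exist_ok=True)
        for name, df in tables.items():
            df.to_csv(qdir / f"{name.upper()}.txt", sep="$", index=False, lineterminator="\n")
        retained.update(ret_q)
        versions.update(ver_q)
        target_caseids.extend(tgt_q)

    gt = GroundTruth(
        retained=retained,
        versions=versions,
        target_caseids=sorted(target_caseids),
        signals=_expected_signal_stats(config),
        pt_soc=config.pt_soc(),
        expected_target_events=config.n_cases * config.target_fraction * config.mean_events_per_case,
        expected_total_events=config.n_cases * config.mean_events_per_case,
        n_cases=config.n_cases,
        seed=config.seed,
    )
    gt.to_json(out / "ground_truth.json")
    with (out / "synthetic_meddra.txt").open("w") as fh:
        for pt, (soc_name, soc_code) in sorted(gt.pt_soc.items()):
            fh.write(f"{pt}${soc_name}${soc_code}\n")
    return gt
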