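"""CSV interchange, study bundles, and the two experiment pipelines.

Canonical schemas (all plain CSV):

tracer.csv   subject_id, group, compartment {dam_plasma, litter_urine},
             time_h, concentration, units {gpg, ppm}
doses.csv    subject_id, group, d2o_mass_g, dam_body_mass_g, purity,
             litter_mass_g, litter_size
wsw.csv      litter_id, group, pnd, pre_weight_g, post_weight_g,
             duration_h, litter_size
truth.csv    (synthetic studies only) per-dam true rates, pools, milk flow

Concentrations are normalised to g D2O per g body water on read (ppm rows
are divided by 1e6).  ``run_experiment1`` chains baseline subtraction,
dilution-based dam body-water estimation, the compartmental fit and the
exact Mann-Whitney group comparison; ``run_experiment2`` summarises WSW
sessions per day with Welch tests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import (
    DAM_PLASMA,
    LITTER_URINE,
    EnrichmentSeries,
    FitConfig,
    fit_bicompartmental,
    subtract_baseline,
)
from .model import NATURAL_ABUNDANCE_PPM, Dose, ppm_to_gpg
from .stats import GroupSample, exact_mann_whitney, median_quartiles, welch_t_test
from .wsw import SucklingSession, wsw_dam_production

__all__ = [
    "StudyBundle",
    "read_tracer_csv",
    "read_dose_csv",
    "read_wsw_csv",
    "read_bundle",
    "write_bundle",
    "run_experiment1",
    "run_experiment2",
]

logger = logging.getLogger(__name__)

TRACER_COLUMNS = ["subject_id", "group", "compartment", "time_h", "concentration"]
DOSE_COLUMNS = ["subject_id", "group", "d2o_mass_g", "dam_body_mass_g", "purity"]
WSW_COLUMNS = ["litter_id", "group", "pnd", "pre_weight_g", "post_weight_g",
               "duration_h", "litter_size"]
_UNITS = ("gpg", "ppm")


@dataclass
class StudyBundle:
    """All tables of one study, plus the generating config when synthetic."""

    tracer: pd.DataFrame
    doses: pd.DataFrame
    wsw: pd.DataFrame | None = None
    truth: pd.DataFrame | None = None
    config: object = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Check cross-table consistency (dose linkage, group labels)."""
        if not self.tracer.empty:
            dosed = set(self.doses["subject_id"])
            orphans = set(self.tracer["subject_id"]) - dosed
            if orphans:
                raise ValueError(f"tracer subjects without a dose record: {sorted(orphans)}")
            merged = self.tracer.merge(self.doses[["subject_id", "group"]],
                                       on="subject_id", suffixes=("", "_dose"))
            bad = merged[merged["group"] != merged["group_dose"]]
            if not bad.empty:
                raise ValueError(
                    f"inconsistent group labels for subjects {sorted(set(bad['subject_id']))}"
                )


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_tracer_csv(path, default_units: str = "gpg") -> pd.DataFrame:
    """Read and validate a tracer table, normalising concentrations to g/g.

    An optional ``units`` column ('gpg' or 'ppm') sets per-row units;
    otherwise ``default_units`` applies to the file.  Errors name the
    offending CSV row (1-based, header excluded).
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, TRACER_COLUMNS, path)
    units = df["units"] if "units" in df.columns else pd.Series(default_units, index=df.index)
    bad_units = units[~units.isin(_UNITS)]
    if not bad_units.empty:
        row = bad_units.index[0] + 1
        raise ValueError(f"{path}, row {row}: unknown units {bad_units.iloc[0]!r} "
                         f"(expected one of {_UNITS})")
    bad_comp = df[~df["compartment"].isin((DAM_PLASMA, LITTER_URINE))]
    if not bad_comp.empty:
        row = bad_comp.index[0] + 1
        raise ValueError(
            f"{path}, row {row}: unknown compartment {bad_comp['compartment'].iloc[0]!r}"
        )
    df = df.copy()
    df["concentration"] = np.where(units == "ppm",
                                   df["concentration"] / 1e6, df["concentration"])
    df["units"] = "gpg"
    for (sid, comp), sub in df.groupby(["subject_id", "compartment"], sort=False):
        t = sub["time_h"].to_numpy(dtype=float)
        if np.any(t < 0):
            offender = sub.index[int(np.argmax(t < 0))] + 1
            raise ValueError(f"{path}, row {offender}: negative time for {sid}/{comp}")
        not_increasing = np.diff(t) <= 0
        if not_increasing.any():
            offender = sub.index[int(np.argmax(not_increasing)) + 1] + 1
            raise ValueError(
                f"{path}, row {offender}: times for {sid}/{comp} must be strictly increasing"
            )
    return df


def read_dose_csv(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, DOSE_COLUMNS, path)
    dup = df[df["subject_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate dose records for {sorted(set(dup['subject_id']))}")
    return df


def read_wsw_csv(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, WSW_COLUMNS, path)
    nonpos = df[df["duration_h"] <= 0]
    if not nonpos.empty:
        raise ValueError(f"{path}, row {nonpos.index[0] + 1}: duration_h must be positive")
    return df


def read_bundle(directory) -> StudyBundle:
    """Load a bundle written by :func:`write_bundle`."""
    directory = Path(directory)
    tracer = read_tracer_csv(directory / "tracer.csv")
    doses = read_dose_csv(directory / "doses.csv")
    wsw = read_wsw_csv(directory / "wsw.csv") if (directory / "wsw.csv").exists() else None
    truth_path = directory / "truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else None
    config = None
    cfg_path = directory / "config.json"
    if cfg_path.exists():
        config = json.loads(cfg_path.read_text())
    return StudyBundle(tracer=tracer, doses=doses, wsw=wsw, truth=truth, config=config)


def _config_to_jsonable(config) -> object:
    if config is None or isinstance(config, dict):
        return config
    if dataclasses.is_dataclass(config):
        return dataclasses.asdict(config)
    return str(config)


def write_bundle(bundle: StudyBundle, directory) -> Path:
    """Write a bundle as CSV files (+ config snapshot) into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bundle.tracer.to_csv(directory / "tracer.csv", index=False, float_format="%.17g")
    bundle.doses.to_csv(directory / "doses.csv", index=False, float_format="%.17g")
    if bundle.wsw is not None:
        bundle.wsw.to_csv(directory / "wsw.csv", index=False, float_format="%.17g")
    if bundle.truth is not None:
        bundle.truth.to_csv(directory / "truth.csv", index=False, float_format="%.17g")
    cfg = _config_to_jsonable(bundle.config)
    if cfg is not None:
        (directory / "config.json").write_text(json.dumps(cfg, indent=2, default=list))
    return directory


def bundle_series(bundle: StudyBundle, subject_id: str, compartment: str) -> EnrichmentSeries:
    """Extract one subject/compartment series (raw, g/g) from a bundle."""
    sub = bundle.tracer[(bundle.tracer["subject_id"] == subject_id)
                        & (bundle.tracer["compartment"] == compartment)]
    if sub.empty:
        raise KeyError(f"no {compartment} series for subject {subject_id!r}")
    return EnrichmentSeries(
        subject_id=subject_id,
        group=str(sub["group"].iloc[0]),
        compartment=compartment,
        times_h=sub["time_h"].to_numpy(dtype=float),
        concentrations=sub["concentration"].to_numpy(dtype=float),
    )


def _dose_for(bundle: StudyBundle, subject_id: str) -> tuple[Dose, float | None]:
    row = bundle.doses[bundle.doses["subject_id"] == subject_id]
    if row.empty:
        raise KeyError(f"no dose record for subject {subject_id!r}")
    row = row.iloc[0]
    dose = Dose(d2o_mass=float(row["d2o_mass_g"]),
                dam_body_mass=float(row["dam_body_mass_g"]),
                purity=float(row.get("purity", 0.999)))
    litter_mass = float(row["litter_mass_g"]) if "litter_mass_g" in row.index else None
    return dose, litter_mass


@dataclass
class Experiment1Report:
    """Per-dam fits plus group summaries and tests for the tracer study."""

    per_dam: pd.DataFrame
    summaries: dict
    tests: dict
    notices: list
    fits: list

    def to_json(self) -> str:
        payload = {
            "per_dam": self.per_dam.to_dict(orient="records"),
            "summaries": self.summaries,
            "tests": self.tests,
            "notices": self.notices,
        }
        return json.dumps(payload, indent=2)


#: Default litter water fraction used to fix the litter pool from litter mass.
LITTER_WATER_FRACTION = 0.76


def run_experiment1(bundle: StudyBundle, config: FitConfig | None = None,
                    baseline_ppm: float = NATURAL_ABUNDANCE_PPM) -> Experiment1Report:
    """Tracer experiment: baseline-correct, estimate TBW, fit, compare groups.

    Per dam: subtract the natural-abundance baseline, estimate the dam's
    body-water pool from the dilution intercept, fit the two-pool model
    (litter pool fixed at litter mass x 0.76 unless the config overrides),
    and derive milk flow.  Group endpoints (TBW mass, milk flow) are
    summarised as median/quartiles/[min; max] and compared across the
    first two groups with the exact Mann-Whitney test.  Dams whose fit
    fails to converge are excluded from summaries with a warning.
    """
    baseline = ppm_to_gpg(baseline_ppm)
    rows, fits, notices = [], [], []
    for sid in bundle.doses["subject_id"]:
        dose, litter_mass = _dose_for(bundle, sid)
        dam = subtract_baseline(bundle_series(bundle, sid, DAM_PLASMA), baseline)
        lit = subtract_baseline(bundle_series(bundle, sid, LITTER_URINE), baseline)
        cfg = config or FitConfig()
        if cfg.tbw_litter_mass is None and not cfg.free_tbwl:
            if litter_mass is None:
                raise ValueError(
                    f"{sid}: litter_mass_g missing from dose table and no "
                    "tbw_litter_mass configured; cannot fix the litter pool"
                )
            cfg = dataclasses.replace(cfg, tbw_litter_mass=LITTER_WATER_FRACTION * litter_mass)
        fit = fit_bicompartmental(dam, lit, dose, cfg)
        fits.append(fit)
        if not fit.converged:
            notices.append(f"{sid}: fit did not converge; excluded from group summaries")
            logger.warning("%s: fit did not converge; excluded from summaries", sid)
        rows.append({
            "subject_id": sid,
            "group": fit.group,
            "tbw_mass_g": fit.tbw.mass,
            "tbw_fraction_pct": 100.0 * fit.tbw.fraction,
            "k_out_dam": fit.rates.k_out_dam,
            "k_dam_to_litter": fit.rates.k_dam_to_litter,
            "k_out_litter": fit.rates.k_out_litter,
            "k_dam_to_litter_sd": fit.param_sd["k_dam_to_litter"],
            "k_dam_to_litter_cv_pct": fit.param_cv["k_dam_to_litter"],
            "milk_flow_g_per_h": fit.milk_flow,
            "milk_flow_sd": fit.milk_flow_sd,
            "objective": fit.objective,
            "converged": fit.converged,
        })
    per_dam = pd.DataFrame(rows)
    usable = per_dam[per_dam["converged"]]

    summaries: dict = {}
    for group, sub in usable.groupby("group", sort=False):
        summaries[group] = {}
        for endpoint in ("tbw_mass_g", "tbw_fraction_pct", "k_dam_to_litter",
                         "milk_flow_g_per_h"):
            fn = median_quartiles(sub[endpoint])
            summaries[group][endpoint] = {
                "n": int(len(sub)), "median": fn.median, "q1": fn.q1, "q3": fn.q3,
                "min": fn.minimum, "max": fn.maximum,
            }

    tests: dict = {}
    groups = list(dict.fromkeys(usable["group"]))
    if len(groups) >= 2:
        g1, g2 = groups[:2]
        for endpoint in ("tbw_mass_g", "milk_flow_g_per_h"):
            x = GroupSample(g1, usable.loc[usable["group"] == g1, endpoint].to_numpy())
            y = GroupSample(g2, usable.loc[usable["group"] == g2, endpoint].to_numpy())
            out = exact_mann_whitney(x, y)
            tests[endpoint] = {
                "comparison": f"{g1} vs {g2}", "method": out.method,
                "statistic": out.statistic, "p_two_sided": out.p_two_sided,
                "significant_at_0.05": out.p_two_sided < 0.05,
            }
    else:
        notices.append("fewer than two groups with converged fits; comparison skipped")

    return Experiment1Report(per_dam=per_dam, summaries=summaries, tests=tests,
                             notices=notices, fits=fits)


@dataclass
class Experiment2Report:
    """Per-day WSW production summaries and group tests."""

    per_session: pd.DataFrame
    per_day: pd.DataFrame
    notices: list

    def to_json(self) -> str:
        per_day = self.per_day.where(pd.notna(self.per_day), None)
        return json.dumps({
            "per_day": per_day.to_dict(orient="records"),
            "notices": self.notices,
        }, indent=2)


def run_experiment2(bundle: StudyBundle) -> Experiment2Report:
    """WSW experiment: per-litter production, daily group means, Welch tests.

    The replication unit is the litter (production is a per-dam quantity).
    Days with fewer than two litters in a group report the mean only and
    skip the test; a group absent on a day yields an 'nd' (not determined)
    cell.
    """
    if bundle.wsw is None or bundle.wsw.empty:
        raise ValueError("bundle has no WSW table")
    sess_rows = []
    for _, row in bundle.wsw.iterrows():
        session = SucklingSession(
            litter_id=str(row["litter_id"]), group=str(row["group"]), pnd=int(row["pnd"]),
            pre_weight=float(row["pre_weight_g"]), post_weight=float(row["post_weight_g"]),
            duration=float(row["duration_h"]), litter_size=int(row["litter_size"]),
        )
        sess_rows.append({
            "litter_id": session.litter_id, "group": session.group, "pnd": session.pnd,
            "production_g_per_h": wsw_dam_production(session),
        })
    per_session = pd.DataFrame(sess_rows)

    groups = list(dict.fromkeys(per_session["group"]))
    notices, day_rows = [], []
    for pnd in sorted(per_session["pnd"].unique()):
        day = per_session[per_session["pnd"] == pnd]
        row: dict = {"pnd": int(pnd)}
        samples = {}
        for g in groups:
            vals = day.loc[day["group"] == g, "production_g_per_h"].to_numpy()
            if vals.size == 0:
                row[f"{g}_mean"] = None  # 'nd': not determined
                row[f"{g}_sd"] = None
                row[f"{g}_n"] = 0
                continue
            row[f"{g}_mean"] = float(vals.mean())
            row[f"{g}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else None
            row[f"{g}_n"] = int(vals.size)
            samples[g] = vals
        if len(groups) >= 2 and all(g in samples and samples[g].size >= 2 for g in groups[:2]):
            g1, g2 = groups[:2]
            out = welch_t_test(GroupSample(g1, samples[g1]), GroupSample(g2, samples[g2]))
            row["welch_t"] = out.statistic
            row["p_two_sided"] = out.p_two_sided
        else:
            row["welch_t"] = None
            row["p_two_sided"] = None
            notices.append(f"PND {pnd}: fewer than 2 litters in a group; test skipped")
        day_rows.append(row)
    return Experiment2Report(per_session=per_session, per_day=pd.DataFrame(day_rows),
                             notices=notices)
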