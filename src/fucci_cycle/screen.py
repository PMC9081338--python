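"""Plate-based compound screen scoring.

Reproduces the analysis chain of a live FUCCI proliferation screen: exclude
out-of-focus sites by nucleus count, aggregate retained sites to wells, join
the plate map, normalize the main parameter (% mVenus+ of FUCCI+) to the
control wells of each plate and timepoint, drop over-dispersed treatments,
pick the acquisition timepoint with the lowest control CV, and rank
compounds by normalized activity.

All tables are pandas DataFrames.  Site tables carry columns
``plate_id, well_id, site_id, timepoint_h, n_nuclei, n_blue, n_red,
n_yellow, n_green``; plate maps carry ``well_id, compound_id, role``.
Every exclusion is logged with a machine-readable reason code.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .classify import StateCounts, main_parameter

log = logging.getLogger(__name__)

COUNT_COLS = ["n_blue", "n_red", "n_yellow", "n_green"]
SITE_KEY = ["plate_id", "well_id", "site_id", "timepoint_h"]


def site_qc(sites: pd.DataFrame, n_sd: float = 2.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude sites whose nucleus count is far below the group mean.

    Within each plate x timepoint group, a site is excluded when
    ``n_nuclei < mean - n_sd * SD`` (sample SD over the group) — a one-sided
    rule, since only abnormally low counts indicate focus or acquisition
    failure.  Groups with fewer than 3 sites are passed through with a
    warning.  Returns (retained sites, exclusion log).
    """
    exclusions = []
    retained_parts = []
    for (plate, tp), grp in sites.groupby(["plate_id", "timepoint_h"], sort=False):
        if len(grp) < 3:
            log.warning(
                "site QC skipped for plate %s timepoint %s: only %d sites",
                plate, tp, len(grp),
            )
            retained_parts.append(grp)
            continue
        mean = grp["n_nuclei"].mean()
        sd = grp["n_nuclei"].std(ddof=1)
        cutoff = mean - n_sd * sd
        low = grp["n_nuclei"] < cutoff
        retained_parts.append(grp[~low])
        for _, row in grp[low].iterrows():
            exclusions.append(
                {
                    **{k: row[k] for k in SITE_KEY},
                    "n_nuclei": row["n_nuclei"],
                    "cutoff": cutoff,
                    "reason": "low_nucleus_count",
                }
            )
            log.info(
                "excluded site %s/%s/%s @ %sh: %d nuclei < cutoff %.1f",
                row["plate_id"], row["well_id"], row["site_id"],
                row["timepoint_h"], row["n_nuclei"], cutoff,
            )
    retained = pd.concat(retained_parts, ignore_index=True) if retained_parts else sites.iloc[0:0]
    logdf = pd.DataFrame(exclusions, columns=SITE_KEY + ["n_nuclei", "cutoff", "reason"])
    return retained, logdf


def aggregate_wells(retained_sites: pd.DataFrame, site_combine: str = "sum") -> pd.DataFrame:
    """Aggregate retained sites into per-well summaries.

    The main parameter is computed on counts summed over the well's retained
    sites (``site_combine='sum'``, unbiased under unequal site populations);
    ``'mean'`` instead averages per-site percentages, mirroring a mean-of-
    sites convention.  Wells whose FUCCI+ total is zero are flagged
    ``no_fucci_positive`` and carry NaN.
    """
    if site_combine not in ("sum", "mean"):
        raise ValueError(f"unknown site_combine: {site_combine!r}")
    rows = []
    for (plate, well, tp), grp in retained_sites.groupby(
        ["plate_id", "well_id", "timepoint_h"], sort=True
    ):
        counts = StateCounts(*(int(grp[c].sum()) for c in COUNT_COLS))
        flags = []
        if site_combine == "sum":
            try:
                mp = main_parameter(counts)
            except ValueError:
                mp, flags = np.nan, ["no_fucci_positive"]
        else:
            per_site = []
            for _, srow in grp.iterrows():
                c = StateCounts(*(int(srow[cc]) for cc in COUNT_COLS))
                if c.fucci_positive > 0:
                    per_site.append(main_parameter(c))
            if per_site:
                mp = float(np.mean(per_site))
            else:
                mp, flags = np.nan, ["no_fucci_positive"]
        rows.append(
            {
                "plate_id": plate,
                "well_id": well,
                "timepoint_h": tp,
                "n_sites": len(grp),
                "mean_n_nuclei": grp["n_nuclei"].mean(),
                **{f"mean_{c}": grp[c].mean() for c in COUNT_COLS},
                "main_parameter_pct": mp,
                "qc_flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows)


def normalize_to_control(wells: pd.DataFrame, plate_map: pd.DataFrame) -> pd.DataFrame:
    """Percent-of-control normalization per plate and timepoint.

    Joins the plate map and divides each well's main parameter by the mean
    over that plate-timepoint's control wells, x100, so control wells
    average to 100% by construction.
    """
    merged = wells.merge(plate_map, on="well_id", how="left", validate="many_to_one")
    out = []
    for (plate, tp), grp in merged.groupby(["plate_id", "timepoint_h"], sort=True):
        ctrl = grp.loc[grp["role"] == "control", "main_parameter_pct"].dropna()
        if len(ctrl) == 0:
            raise ValueError(f"no control wells with data on plate {plate} at {tp} h")
        ctrl_mean = ctrl.mean()
        if ctrl_mean == 0:
            raise ValueError(f"control mean is 0 on plate {plate} at {tp} h")
        g = grp.copy()
        g["normalized_pct"] = 100.0 * g["main_parameter_pct"] / ctrl_mean
        out.append(g)
    return pd.concat(out, ignore_index=True)


def summarize_treatments(wells: pd.DataFrame) -> pd.DataFrame:
    """Per-compound mean +/- sample SD of the normalized value across
    replicate wells, per timepoint."""
    rows = []
    for (cid, tp), grp in wells.groupby(["compound_id", "timepoint_h"], sort=True):
        vals = grp["normalized_pct"].dropna()
        rows.append(
            {
                "compound_id": cid,
                "timepoint_h": tp,
                "role": grp["role"].iloc[0],
                "n_wells": len(vals),
                "normalized_mean_pct": vals.mean() if len(vals) else np.nan,
                "normalized_sd_pct": vals.std(ddof=1) if len(vals) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def treatment_qc(result: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude over-dispersed treatments.

    A compound is excluded at a timepoint when the replicate SD exceeds half
    the mean (equality retains).  Single-replicate entries cannot be judged
    and are flagged ``single_replicate``.  Returns (result with
    retained/excluded status, exclusion log).
    """
    out = result.copy()
    status, reasons, exclusions = [], [], []
    for _, row in out.iterrows():
        if row["n_wells"] < 2:
            status.append("flagged")
            reasons.append("single_replicate")
            continue
        if row["normalized_sd_pct"] > row["normalized_mean_pct"] / 2.0:
            status.append("excluded")
            reasons.append("replicate_dispersion")
            exclusions.append(
                {
                    "compound_id": row["compound_id"],
                    "timepoint_h": row["timepoint_h"],
                    "mean": row["normalized_mean_pct"],
                    "sd": row["normalized_sd_pct"],
                    "reason": "replicate_dispersion",
                }
            )
            log.info(
                "excluded compound %s @ %sh: SD %.1f > mean/2 %.1f",
                row["compound_id"], row["timepoint_h"],
                row["normalized_sd_pct"], row["normalized_mean_pct"] / 2,
            )
        else:
            status.append("retained")
            reasons.append("")
    out["status"] = status
    out["reason"] = reasons
    logdf = pd.DataFrame(
        exclusions, columns=["compound_id", "timepoint_h", "mean", "sd", "reason"]
    )
    return out, logdf


def select_timepoint(wells: pd.DataFrame) -> tuple[float, pd.DataFrame]:
    """Acquisition timepoint with the smallest control-well CV.

    CV = 100 * SD / mean of the normalized main parameter over control wells
    at each timepoint; ties break toward the earlier timepoint.
    """
    ctrl = wells[wells["role"] == "control"]
    rows = []
    for tp, grp in ctrl.groupby("timepoint_h", sort=True):
        vals = grp["normalized_pct"].dropna()
        if len(vals) < 2:
            continue
        cv = 100.0 * vals.std(ddof=1) / vals.mean()
        rows.append({"timepoint_h": tp, "control_cv_pct": cv, "n_control_wells": len(vals)})
    table = pd.DataFrame(rows)
    if len(table) < 2:
        raise ValueError("timepoint selection needs >= 2 timepoints with >= 2 control wells")
    # stable sort keeps the earlier timepoint first on ties
    best = table.sort_values("timepoint_h").sort_values("control_cv_pct", kind="stable")
    return float(best["timepoint_h"].iloc[0]), table


def rank_hits(result: pd.DataFrame, timepoint_h: float) -> pd.DataFrame:
    """Retained compounds at the chosen timepoint, ordered by descending
    normalized mean; ties break by lower replicate SD, then compound id."""
    sel = result[
        (result["timepoint_h"] == timepoint_h)
        & (result["role"] == "compound")
        & (result["status"] == "retained")
    ].copy()
    sel = sel.sort_values(
        ["normalized_mean_pct", "normalized_sd_pct", "compound_id"],
        ascending=[False, True, True],
        kind="stable",
    ).reset_index(drop=True)
    sel["rank"] = np.arange(1, len(sel) + 1)
    return sel


def run_screen(
    sites: pd.DataFrame,
    plate_map: pd.DataFrame,
    site_combine: str = "sum",
    exclude_baseline_timepoint: bool = True,
) -> dict:
    """Full screen chain: site QC -> wells -> normalization -> treatment QC
    -> timepoint selection -> ranking.  Returns all intermediates.

    The 0-h acquisition (taken before compounds act) is excluded from
    timepoint selection and ranking when present.
    """
    retained, site_log = site_qc(sites)
    wells = aggregate_wells(retained, site_combine=site_combine)
    wells = normalize_to_control(wells, plate_map)
    result = summarize_treatments(wells)
    result, treat_log = treatment_qc(result)
    sel_wells = wells[wells["timepoint_h"] > 0] if exclude_baseline_timepoint else wells
    best_tp, cv_table = select_timepoint(sel_wells)
    ranked = rank_hits(result, best_tp)
    return {
        "retained_sites": retained,
        "site_exclusions": site_log,
        "wells": wells,
        "result": result,
        "treatment_exclusions": treat_log,
        "selected_timepoint_h": best_tp,
        "cv_table": cv_table,
        "ranked": ranked,
    }
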