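"""Run summaries: class proportions, ground-truth scoring, report files."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["class_proportions", "score_against_truth", "write_report"]

RESPONSIVE_CLASSES = ("onset", "sustained", "inhibited", "offset", "mixed")


def class_proportions(
    fra_table: pd.DataFrame, genotype: str | None = None
) -> pd.DataFrame:
    """Counts and fractions of FRA classes among responsive cells.

    Emits both granularities: the four-way split with onset and sustained
    merged as "excitatory", and the full five-way split.  The responsive
    fraction among all cells rides along in the attrs.
    """
    df = fra_table
    if genotype is not None:
        df = df[df["genotype"] == genotype]
    n_total = len(df)
    resp = df[df["fra_type"].isin(RESPONSIVE_CLASSES)]
    n_resp = len(resp)
    counts = resp["fra_type"].value_counts()
    rows = []
    merged = {
        "excitatory": int(counts.get("onset", 0) + counts.get("sustained", 0)),
        "inhibited": int(counts.get("inhibited", 0)),
        "offset": int(counts.get("offset", 0)),
        "mixed": int(counts.get("mixed", 0)),
    }
    for name, cnt in merged.items():
        rows.append(
            {"granularity": "merged", "fra_class": name, "count": cnt,
             "fraction": cnt / n_resp if n_resp else np.nan}
        )
    for name in RESPONSIVE_CLASSES:
        cnt = int(counts.get(name, 0))
        rows.append(
            {"granularity": "full", "fra_class": name, "count": cnt,
             "fraction": cnt / n_resp if n_resp else np.nan}
        )
    out = pd.DataFrame(rows)
    out.attrs["n_total"] = n_total
    out.attrs["n_responsive"] = n_resp
    out.attrs["responsive_fraction"] = n_resp / n_total if n_total else np.nan
    return out


def score_against_truth(
    results: pd.DataFrame, truth: pd.DataFrame
) -> dict:
    """Score a synthetic run against its generator's ground truth.

    Returns the class confusion matrix (true x estimated), the overall
    class agreement, and the CF error distribution in octaves for tuned
    cells.  The truth label "movement" maps onto "none": movement-coupled
    cells have no tone-evoked FRA.
    """
    if set(results["roi_id"]) != set(truth["roi_id"]):
        raise ValueError("roi_ids of results and truth do not match")
    merged = truth.merge(results, on="roi_id", suffixes=("_true", "_est"))
    true_cls = merged["true_class"].replace({"movement": "none"})
    est_cls = merged["fra_type"]
    confusion = pd.crosstab(true_cls, est_cls, dropna=False)
    agreement = float((true_cls == est_cls).mean())

    tuned = merged[
        merged["true_class"].isin(("onset", "sustained", "inhibited", "offset"))
        & np.isfinite(merged["cf_khz"])
    ]
    cf_err_oct = np.log2(tuned["cf_khz"] / tuned["true_cf_khz"]).to_numpy()
    return {
        "confusion": confusion,
        "class_agreement": agreement,
        "cf_error_octaves": cf_err_oct,
        "cf_median_abs_error_oct": float(np.median(np.abs(cf_err_oct)))
        if len(cf_err_oct)
        else np.nan,
        "n_cells": len(merged),
        "n_tuned_with_cf": len(tuned),
    }


def write_report(
    out_dir: str | Path,
    fra_table: pd.DataFrame,
    scoring: dict | None = None,
    tonotopy_summary: dict | None = None,
    seeds: dict | None = None,
) -> Path:
    """Write the CSV + JSON report bundle for one pipeline run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fra_table.to_csv(out / "fra_results.csv", index=False, float_format="%.8g")
    props = class_proportions(fra_table)
    props.to_csv(out / "class_proportions.csv", index=False, float_format="%.8g")
    summary = {
        "n_total": props.attrs["n_total"],
        "n_responsive": props.attrs["n_responsive"],
        "responsive_fraction": props.attrs["responsive_fraction"],
        "seeds": seeds or {},
    }
    if tonotopy_summary:
        summary["tonotopy"] = tonotopy_summary
    if scoring:
        scoring = dict(scoring)
        confusion = scoring.pop("confusion")
        confusion.to_csv(out / "confusion.csv")
        scoring["cf_error_octaves"] = [float(v) for v in scoring["cf_error_octaves"]]
        summary["scoring"] = scoring
    with open(out / "report.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=float)
    return out / "report.json"
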