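"""Bundled reference tables."""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_cohort_demographics() -> pd.DataFrame:
    """Demographic/clinical bookkeeping table of the published 61-patient
    multicenter iEEG cohort (per-patient seizure counts, implanted channel
    counts, SOZ channel counts, and implantation type).

    Used for protocol bookkeeping (cohort totals, channel-count ranges) and
    as the template for realistic synthetic cohort sizes; it contains no
    signal data.
    """
    with resources.files("ieegflow.data").joinpath(
            "multicenter_demographics.csv").open() as fh:
        return pd.read_csv(fh)


def cohort_bookkeeping() -> dict:
    """Totals and ranges recomputed from the demographics table."""
    d = load_cohort_demographics()
    return {
        "n_patients": int(len(d)),
        "n_seizures_total": int(d["n_seizures"].sum()),
        "mean_channels": float(d["n_channels"].mean()),
        "min_channels": int(d["n_channels"].min()),
        "max_channels": int(d["n_channels"].max()),
        "median_seizures_per_patient": float(d["n_seizures"].median()),
    }
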