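"""Packaged reference data.

``load_cohort`` returns the bundled 11-patient clinical cohort (eye-canthus
electron therapy with 3D-printed and paraffin boluses): per-patient planning
parameters, reported bolus volumes with Matching Level indices, and
per-metric dose-difference percentages.  These printed values serve as
regression anchors for the ML and summary-statistics conventions.
"""

from __future__ import annotations

import json
from importlib import resources

__all__ = ["load_cohort", "cohort_column"]


def load_cohort() -> dict:
    with resources.files("bolusforge.data").joinpath("cohort.json").open() as fh:
        return json.load(fh)


def cohort_column(key: str, cohort: dict | None = None) -> list[float]:
    """One per-patient column (in patient-id order) from the cohort."""
    cohort = cohort or load_cohort()
    patients = sorted(cohort["patients"], key=lambda p: p["id"])
    if key not in patients[0]:
        raise KeyError(key)
    return [float(p[key]) for p in patients]
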