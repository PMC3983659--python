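"""Bundled worked-example data: in-vivo assayed liver enhancer predictions.

A small table of 12 liver enhancer predictions and 5 negative-control
regions (hg18 coordinates, converted to 0-based half-open) that were tested
for enhancer activity in mouse liver by the hydrodynamic tail-vein injection
assay. Scores are the liver promoter-model decision values; ``activity``
records whether the region drove significant luciferase expression. The
table serves as a worked example for the reporting statistics (mean scores,
activity rates) - the assay itself is outside this package's scope.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_invivo_liver_assay", "assay_summary"]


def load_invivo_liver_assay() -> pd.DataFrame:
    """The assayed prediction/control table as a DataFrame."""
    ref = resources.files("promsig.data").joinpath("invivo_liver_assay.tsv")
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t")


def assay_summary(df: pd.DataFrame | None = None) -> dict:
    """Mean model scores and activity rates per assay set.

    Returns, for predictions and controls separately, the number of regions,
    the mean decision score, the count with significant in-vivo activity, and
    the activity fraction.
    """
    if df is None:
        df = load_invivo_liver_assay()
    out: dict = {}
    for name, sub in df.groupby("set"):
        active = int((sub["activity"] == "yes").sum())
        out[name] = {
            "n": int(len(sub)),
            "mean_score": float(sub["score"].mean()),
            "n_active": active,
            "activity_fraction": active / len(sub),
        }
    return out
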