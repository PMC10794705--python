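"""Bundled reference data.

Two small TSVs ship with the package, taken from a published five-pipeline
mock-community benchmark (bioBakery3, bioBakery4, JAMS, WGSA2, Woltka over
eleven mock communities):

* per-community mean (and, for replicate communities, SD) of the three
  accuracy metrics — Aitchison distance, sensitivity and FPRA;
* per-organism F1 scores from the five-sample panel confusion-matrix
  analysis at the 0% and 0.01% thresholds, with missing cells preserved.

They serve as regression fixtures for the aggregation layer: feeding the
printed community means back through the summary operations must
reproduce the printed grand averages, and the F1 columns must reproduce
the printed harmonic means.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

PIPELINES = ("bioBakery3", "bioBakery4", "JAMS", "WGSA2", "Woltka")


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("taxabench").joinpath(f"data/{name}")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_benchmark_means() -> pd.DataFrame:
    """Per-community mean/SD cells for AD, Sensitivity and FPRA.

    Columns: metric, community_id, n, pipeline_id, mean, sd (NaN for
    single-sample communities).
    """
    return _read("benchmark_metric_means.tsv")


def load_benchmark_f1() -> pd.DataFrame:
    """Per-organism F1 cells from the panel confusion-matrix analysis.

    Columns: threshold_pct, organism, pipeline_id, f1 (NaN = score
    undefined for that organism/pipeline).
    """
    return _read("benchmark_f1_scores.tsv")
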