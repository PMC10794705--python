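"""Per-sample accuracy metrics for profiler output against ground truth.

The primary metric is the Aitchison distance (AD): relative abundances
are compositional, so expected and observed vectors are compared in
CLR (centered log-ratio) space, where Euclidean distance is meaningful.
Zeros — inevitable once expected and observed taxon sets are unioned —
are imputed by multiplicative replacement before the log-ratio step.

Alongside AD: sensitivity (percent of expected species detected at any
positive abundance), total false-positive relative abundance (FPRA; the
share of observed signal assigned to taxa absent from the truth), and
the unclassified percentage where the dialect reports one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, ValidationError
from .profiles import AbundanceProfile, ExpectedComposition

DEFAULT_FP_FILTER_PCT = 0.01


@dataclass
class JoinedProfile:
    """Union of expected and observed taxa for one (sample, pipeline).

    One row per TAXID; a taxon absent from one side carries 0 there.
    The union (rather than an expected-only left join) is essential: AD
    must be penalized for extraneous species and FPRA needs the
    observed-only rows.
    """

    sample_id: str
    pipeline_id: str
    community_id: str
    rows: pd.DataFrame  # columns: taxid, name, expected_pct, observed_pct

    def expected_taxa(self) -> pd.DataFrame:
        return self.rows[self.rows.expected_pct > 0]

    def false_positive_taxa(self) -> pd.DataFrame:
        return self.rows[(self.rows.expected_pct == 0) & (self.rows.observed_pct > 0)]


@dataclass
class SampleMetrics:
    sample_id: str
    pipeline_id: str
    community_id: str
    ad: float
    sensitivity_pct: float
    fpra_pct: float
    unclassified_pct: Optional[float]


def join_profiles(
    expected: ExpectedComposition, observed: AbundanceProfile
) -> JoinedProfile:
    """Union-join expected and observed abundances on TAXID."""
    exp = expected.by_taxid()
    obs = observed.by_taxid()
    taxids = list(exp) + [t for t in obs if t not in exp]
    rows = pd.DataFrame(
        {
            "taxid": taxids,
            "name": [
                (exp[t].name if t in exp else obs[t].name) for t in taxids
            ],
            "expected_pct": [exp[t].rel_abund if t in exp else 0.0 for t in taxids],
            "observed_pct": [obs[t].rel_abund if t in obs else 0.0 for t in taxids],
        }
    )
    return JoinedProfile(
        observed.sample_id, observed.pipeline_id, expected.community_id, rows
    )


def filter_low_fp(
    joined: JoinedProfile, threshold_pct: float = DEFAULT_FP_FILTER_PCT
) -> JoinedProfile:
    """Drop false-positive taxa observed below ``threshold_pct`` percent.

    Only rows with zero expected abundance are ever removed; expected taxa
    are retained no matter how faintly (or not at all) they were observed.
    """
    if threshold_pct < 0:
        raise ValueError("threshold_pct must be >= 0")
    keep = (joined.rows.expected_pct > 0) | (joined.rows.observed_pct >= threshold_pct)
    return JoinedProfile(
        joined.sample_id,
        joined.pipeline_id,
        joined.community_id,
        joined.rows[keep].reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# compositional core


def closure(values: Sequence[float]) -> np.ndarray:
    """Scale a non-negative vector to sum to 1."""
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise ValidationError("composition has negative components")
    total = arr.sum()
    if total <= 0:
        raise DegenerateInputError("composition sums to zero")
    return arr / total


def multiplicative_replacement(
    comp: Sequence[float], delta: Optional[float] = None
) -> np.ndarray:
    """Impute zeros in a composition, preserving closure.

    Zeros become ``delta`` (default ``(1/D)**2`` for a vector of length D)
    and non-zero components are shrunk by the factor ``1 - delta*z`` where
    ``z`` is the number of zeros, so the result still sums to 1.
    """
    arr = np.asarray(comp, dtype=float)
    if np.any(arr < 0):
        raise ValidationError("composition has negative components")
    if not math.isclose(arr.sum(), 1.0, abs_tol=1e-9):
        raise ValidationError(
            f"multiplicative replacement expects a closed composition, sum={arr.sum()}"
        )
    zeros = arr == 0
    z = int(zeros.sum())
    if z == 0:
        return arr.copy()
    if delta is None:
        delta = (1.0 / len(arr)) ** 2
    if delta <= 0:
        raise ValueError("delta must be positive")
    if delta * z >= 1:
        raise ValueError(
            f"delta={delta} with {z} zeros would exceed the unit simplex"
        )
    out = arr * (1.0 - delta * z)
    out[zeros] = delta
    return out


def clr(comp: Sequence[float]) -> np.ndarray:
    """Centered log-ratio transform: log of each part over the geometric mean.

    Scale-invariant, so it accepts counts, percentages or proportions; the
    output always sums to zero.
    """
    arr = np.asarray(comp, dtype=float)
    if np.any(arr <= 0):
        raise ValidationError("CLR requires strictly positive components")
    log = np.log(arr)
    return log - log.mean()


def aitchison_distance(
    x: Sequence[float],
    y: Sequence[float],
    delta: Optional[float] = None,
) -> float:
    """Aitchison distance: Euclidean distance between CLR-transformed vectors.

    Both vectors must cover the same taxa in the same order.  Zeros are
    allowed; each vector is closed to proportions and zero-imputed by
    multiplicative replacement before the transform.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    cx = clr(multiplicative_replacement(closure(x), delta))
    cy = clr(multiplicative_replacement(closure(y), delta))
    return float(np.linalg.norm(cx - cy))


# ---------------------------------------------------------------------------
# scalar metrics


def sensitivity(joined: JoinedProfile) -> float:
    """Percent of expected species detected at any positive abundance."""
    expected = joined.rows.expected_pct > 0
    n_expected = int(expected.sum())
    if n_expected == 0:
        raise DegenerateInputError("no expected taxa in joined profile")
    hits = int((expected & (joined.rows.observed_pct > 0)).sum())
    return 100.0 * hits / n_expected


def fpra(joined: JoinedProfile) -> float:
    """Total false-positive relative abundance, percent of observed signal.

    Only annotated species count: the unclassified fraction is never a
    false positive, and over-estimated expected taxa contribute nothing.
    """
    total = joined.rows.observed_pct.sum()
    if total <= 0:
        raise DegenerateInputError("no observed abundance in joined profile")
    fp_mass = joined.rows.loc[joined.rows.expected_pct == 0, "observed_pct"].sum()
    return float(100.0 * fp_mass / total)


def unclassified_pct(
    profiles: Union[AbundanceProfile, Iterable[AbundanceProfile]]
) -> Optional[float]:
    """Unclassified percentage of a profile, or the mean over replicates.

    ``None`` when the dialect does not report an unclassified fraction.
    """
    if isinstance(profiles, AbundanceProfile):
        return profiles.unclassified_pct
    values = [p.unclassified_pct for p in profiles if p.unclassified_pct is not None]
    return float(np.mean(values)) if values else None


def evaluate_sample(
    expected: ExpectedComposition,
    observed: AbundanceProfile,
    fp_filter_pct: float = DEFAULT_FP_FILTER_PCT,
    delta: Optional[float] = None,
) -> SampleMetrics:
    """Compute all per-sample metrics for one (expected, observed) pair.

    The low-abundance false-positive filter is applied once, before any
    metric; AD is then computed on the union taxon set with both sides
    closed to proportions.
    """
    joined = filter_low_fp(join_profiles(expected, observed), fp_filter_pct)
    ad = aitchison_distance(
        joined.rows.expected_pct.to_numpy(),
        joined.rows.observed_pct.to_numpy(),
        delta=delta,
    )
    return SampleMetrics(
        sample_id=observed.sample_id,
        pipeline_id=observed.pipeline_id,
        community_id=expected.community_id,
        ad=ad,
        sensitivity_pct=sensitivity(joined),
        fpra_pct=fpra(joined),
        unclassified_pct=observed.unclassified_pct,
    )


def metrics_frame(metrics: Iterable[SampleMetrics]) -> pd.DataFrame:
    """Long-format metrics table (one row per sample x pipeline)."""
    return pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in metrics],
            "pipeline_id": [m.pipeline_id for m in metrics],
            "community_id": [m.community_id for m in metrics],
            "ad": [m.ad for m in metrics],
            "sensitivity_pct": [m.sensitivity_pct for m in metrics],
            "fpra_pct": [m.fpra_pct for m in metrics],
            "unclassified_pct": [m.unclassified_pct for m in metrics],
        }
    )


def heatmap_export(
    expected: ExpectedComposition, observed: Iterable[AbundanceProfile]
) -> pd.DataFrame:
    """Long-format, unfiltered expected-left join with log10 abundances.

    Mirrors the qualitative heatmap layout: expected taxa only, one column
    of log10 expected values and one per pipeline; zeros export as empty
    cells (NaN) so they render as missing.
    """
    exp = expected.by_taxid()
    out = pd.DataFrame(
        {
            "taxid": list(exp),
            "name": [r.name for r in exp.values()],
            "expected": [math.log10(r.rel_abund) for r in exp.values()],
        }
    )
    for prof in observed:
        obs = prof.by_taxid()
        out[prof.pipeline_id] = [
            math.log10(obs[t].rel_abund)
            if t in obs and obs[t].rel_abund > 0
            else np.nan
            for t in exp
        ]
    return out
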