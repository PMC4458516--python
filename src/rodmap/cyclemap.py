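"""Cell-cycle-resolved population statistics.

In a steady-state exponentially growing culture the distribution of
cell-cycle ages is time-invariant with density p(a) = 2 ln2 · 2^(−a) and
CDF F(a) = 2 (1 − 2^(−a)), a ∈ [0, 1].  Under exponential single-cell
growth L(a) = L0 · 2^a, length rank is a monotone proxy for age, so a
cell's age can be assigned by inverting the CDF at its mid-rank fraction:

    F = (rank − 0.5) / n,        a = −log2(1 − F / 2).

Stacking the length-normalized axial profiles of a length-sorted
population gives the profile map (demograph); binning cells into 10%
age classes and averaging gives the class profiles from which mid-cell
recruitment timing is read.

Two per-cell mid-cell statistics are provided, both over an absolute
0.8 µm axial window centred at mid-cell:

* **ring fraction** — fluorescence inside the window divided by the
  cell's total fluorescence;
* **FCplus** — fluorescence inside the window in excess of a baseline
  estimated from two flanking windows of the same width, clipped at 0.

Population summaries of FCplus over age classes define the *initiation*
(first class where the mid-cell excess rises above the pre-divisional
baseline) and the *moment* (class of maximal excess).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._geom import window_overlap_weights
from .errors import ConsistencyError
from .profile import AxialProfile

#: Mid-cell rectangle width, µm (also the default FCplus flank width).
DEFAULT_WINDOW_UM = 0.8
#: Number of equal-width cell-cycle age classes.
DEFAULT_N_CLASSES = 10


def assign_ages(lengths, cell_ids=None) -> pd.DataFrame:
    """Assign cell-cycle ages from length ranks.

    Returns a PopulationTable DataFrame with columns cell_id, length_um,
    rank (1-based, ascending length, ties broken by cell_id), rank_fraction
    F = (rank − 0.5)/n and age = −log2(1 − F/2).  Deterministic and
    stable.  Raises ValueError on nonpositive lengths; an empty input
    yields an empty table.
    """
    lengths = np.asarray(lengths, dtype=float)
    n = len(lengths)
    if cell_ids is None:
        cell_ids = np.arange(1, n + 1, dtype=int)
    else:
        cell_ids = np.asarray(cell_ids)
    if n == 0:
        return pd.DataFrame(
            columns=["cell_id", "length_um", "rank", "rank_fraction", "age"]
        )
    if np.any(lengths <= 0):
        raise ValueError("all lengths must be positive")
    order = np.lexsort((cell_ids, lengths))
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    frac = (rank - 0.5) / n
    age = -np.log2(1.0 - frac / 2.0)
    return pd.DataFrame(
        {
            "cell_id": cell_ids,
            "length_um": lengths,
            "rank": rank,
            "rank_fraction": frac,
            "age": age,
        }
    )


@dataclass
class ProfileMap:
    """Length-sorted matrix of length-normalized axial profiles."""

    matrix: np.ndarray          # (n_cells, n_cols), ascending length
    cell_ids: np.ndarray
    lengths_um: np.ndarray
    ages: np.ndarray
    channel: str

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]


def _resample_values(values: np.ndarray, n_cols: int) -> np.ndarray:
    """Linear resampling of per-bin values onto n_cols bins (same mass scale)."""
    nb = len(values)
    if nb == n_cols:
        return np.asarray(values, dtype=float)
    src = (np.arange(nb) + 0.5) / nb
    dst = (np.arange(n_cols) + 0.5) / n_cols
    # interpolate per-bin *density*, then rescale to per-bin mass
    return np.interp(dst, src, np.asarray(values, dtype=float) * nb) / n_cols


def build_profile_map(
    profiles: list[AxialProfile],
    table: pd.DataFrame,
    n_cols: int = 50,
) -> ProfileMap:
    """Stack length-normalized profiles into a demograph matrix.

    Rows follow the PopulationTable's ascending length order (ties broken
    by cell_id); every profile is resampled to `n_cols` columns of
    normalized axial position.  A profile whose cell_id is absent from
    the table raises ConsistencyError.
    """
    by_id = {p.cell_id: p for p in profiles}
    missing = set(by_id) - set(table["cell_id"].tolist())
    if missing:
        raise ConsistencyError(f"profiles for unknown cell_ids: {sorted(missing)}")
    sorted_table = table.sort_values(
        ["length_um", "cell_id"], kind="stable"
    ).reset_index(drop=True)
    sorted_table = sorted_table[sorted_table["cell_id"].isin(by_id)]
    ids = sorted_table["cell_id"].to_numpy()
    matrix = np.vstack([_resample_values(by_id[i].values, n_cols) for i in ids])
    channel = profiles[0].channel if profiles else ""
    return ProfileMap(
        matrix=matrix,
        cell_ids=ids,
        lengths_um=sorted_table["length_um"].to_numpy(dtype=float),
        ages=sorted_table["age"].to_numpy(dtype=float),
        channel=channel,
    )


@dataclass
class AgeClassSummary:
    """Per-age-class profile averages and mid-cell excess statistics.

    Classes partition [0, 1] into `n_classes` equal intervals; empty
    classes are retained with count 0 and NaN profiles (flagged), never
    dropped.  `peak_profiles` are the mean profiles scaled to a maximum
    of 1 where any signal is present.
    """

    edges: np.ndarray                   # (n_classes + 1,)
    counts: np.ndarray                  # (n_classes,)
    mean_profiles: np.ndarray           # (n_classes, n_cols), NaN if empty
    peak_profiles: np.ndarray           # (n_classes, n_cols)
    mean_excess: np.ndarray             # class mean of per-cell FCplus
    var_excess: np.ndarray              # class variance of per-cell FCplus
    n_excess: np.ndarray                # cells with defined FCplus per class

    @property
    def n_classes(self) -> int:
        return len(self.counts)

    @property
    def sem_excess(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.sqrt(self.var_excess / np.maximum(self.n_excess, 1))


def age_class_averages(
    profiles: list[AxialProfile],
    table: pd.DataFrame,
    n_classes: int = DEFAULT_N_CLASSES,
    n_cols: int = 50,
    window_um: float = DEFAULT_WINDOW_UM,
    flank_um: float = DEFAULT_WINDOW_UM,
) -> AgeClassSummary:
    """Average length-normalized profiles within equal-width age classes.

    Also accumulates the per-cell mid-cell excess (FCplus) statistics per
    class, which feed initiation detection.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be at least 2")
    ages = dict(zip(table["cell_id"], table["age"]))
    edges = np.linspace(0.0, 1.0, n_classes + 1)
    sums = np.zeros((n_classes, n_cols))
    counts = np.zeros(n_classes, dtype=int)
    excess_acc: list[list[float]] = [[] for _ in range(n_classes)]
    for p in profiles:
        if p.cell_id not in ages:
            raise ConsistencyError(f"profile for unknown cell_id {p.cell_id}")
        a = ages[p.cell_id]
        k = min(int(a * n_classes), n_classes - 1)
        sums[k] += _resample_values(p.values, n_cols)
        counts[k] += 1
        fc = fc_plus(p.values, p.length_um, window_um=window_um, flank_um=flank_um)
        if np.isfinite(fc):
            excess_acc[k].append(fc)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_profiles = np.where(
            counts[:, None] > 0, sums / np.maximum(counts[:, None], 1), np.nan
        )
    peak_profiles = np.full_like(mean_profiles, np.nan)
    for k in range(n_classes):
        if counts[k] == 0:
            continue
        peak = np.nanmax(mean_profiles[k])
        peak_profiles[k] = mean_profiles[k] / peak if peak > 0 else np.nan

    mean_excess = np.full(n_classes, np.nan)
    var_excess = np.full(n_classes, np.nan)
    n_excess = np.zeros(n_classes, dtype=int)
    for k, acc in enumerate(excess_acc):
        if acc:
            arr = np.asarray(acc)
            mean_excess[k] = arr.mean()
            var_excess[k] = arr.var(ddof=1) if len(arr) > 1 else 0.0
            n_excess[k] = len(arr)
    return AgeClassSummary(
        edges=edges,
        counts=counts,
        mean_profiles=mean_profiles,
        peak_profiles=peak_profiles,
        mean_excess=mean_excess,
        var_excess=var_excess,
        n_excess=n_excess,
    )


def _window_sum(values: np.ndarray, length_um: float, lo: float, hi: float) -> float:
    weights = window_overlap_weights(len(values), length_um, lo, hi)
    return float(np.dot(np.asarray(values, dtype=float), weights))


def ring_fraction(
    profile: AxialProfile | np.ndarray,
    length_um: float | None = None,
    window_um: float = DEFAULT_WINDOW_UM,
) -> float:
    """Fraction of total fluorescence in the central `window_um` rectangle.

    Bins partially covered by the window contribute pro rata (uniform
    density within a bin).  Returns NaN (flagged undefined) when the
    total is not positive.  Requires length > window.
    """
    if isinstance(profile, AxialProfile):
        values, length_um = profile.values, profile.length_um
    else:
        values = np.asarray(profile, dtype=float)
        if length_um is None:
            raise ValueError("length_um required when passing raw values")
    if length_um <= window_um:
        raise ValueError(f"cell length {length_um} must exceed window {window_um}")
    total = float(np.sum(values))
    if total <= 0:
        return float("nan")
    mid = length_um / 2.0
    inside = _window_sum(values, length_um, mid - window_um / 2.0, mid + window_um / 2.0)
    return inside / total


def fc_plus(
    profile: AxialProfile | np.ndarray,
    length_um: float | None = None,
    window_um: float = DEFAULT_WINDOW_UM,
    flank_um: float = DEFAULT_WINDOW_UM,
) -> float:
    """Extra mid-cell fluorescence above the flanking baseline (FCplus).

    FCplus = (window integral) − (mean flank density) × window width,
    where the baseline density is estimated from two windows of width
    `flank_um` immediately adjacent to the mid-cell window; negative
    values are clipped to 0.  Cells too short for the window plus both
    flanks return NaN (flagged undefined).
    """
    if isinstance(profile, AxialProfile):
        values, length_um = profile.values, profile.length_um
    else:
        values = np.asarray(profile, dtype=float)
        if length_um is None:
            raise ValueError("length_um required when passing raw values")
    if length_um <= window_um + 2.0 * flank_um:
        return float("nan")
    mid = length_um / 2.0
    w2 = window_um / 2.0
    window = _window_sum(values, length_um, mid - w2, mid + w2)
    flanks = _window_sum(values, length_um, mid - w2 - flank_um, mid - w2) + _window_sum(
        values, length_um, mid + w2, mid + w2 + flank_um
    )
    baseline_density = flanks / (2.0 * flank_um)
    return max(window - baseline_density * window_um, 0.0)


def detect_initiation(
    summary: AgeClassSummary, n_se: float = 2.0, min_rel_excess: float = 0.05
) -> float | None:
    """Age class (lower bound) where mid-cell enrichment first appears.

    The earliest class whose mean mid-cell excess exceeds the pooled
    excess of all earlier classes by `n_se` combined standard errors,
    with every later (nonempty) class also above that threshold
    (monotonic confirmation).  Because FCplus is clipped at zero and
    length-rank ages smear slightly across class boundaries, a pure
    significance rule can fire one or two classes early on large
    populations; a practical-significance floor of `min_rel_excess`
    times the population's dynamic range (largest class mean above the
    pooled baseline) is therefore also required.  Returns None when no
    class qualifies.  Requires at least 3 nonempty classes.
    """
    defined = np.nonzero(summary.n_excess > 0)[0]
    if len(defined) < 3:
        raise ValueError("need at least 3 nonempty age classes")
    global_max = float(np.nanmax(summary.mean_excess[defined]))
    for c in defined[1:]:
        earlier = defined[defined < c]
        n_pool = int(summary.n_excess[earlier].sum())
        if n_pool == 0:
            continue
        pooled_mean = float(
            np.sum(summary.mean_excess[earlier] * summary.n_excess[earlier]) / n_pool
        )
        # pooled variance across earlier classes (within + between)
        sq = (
            summary.var_excess[earlier] * np.maximum(summary.n_excess[earlier] - 1, 0)
            + summary.n_excess[earlier] * summary.mean_excess[earlier] ** 2
        )
        pooled_var = max(float(sq.sum() / n_pool - pooled_mean**2), 0.0)
        se = float(
            np.sqrt(pooled_var / n_pool + summary.sem_excess[c] ** 2)
        )
        threshold = pooled_mean + max(
            n_se * se, min_rel_excess * (global_max - pooled_mean)
        )
        if summary.mean_excess[c] > threshold:
            later = defined[defined > c]
            if np.all(summary.mean_excess[later] > threshold):
                return float(summary.edges[c])
    return None


def detect_moment(
    fc_values, ages, n_classes: int = DEFAULT_N_CLASSES
) -> float | None:
    """Age (class midpoint) at which population mid-cell excess peaks.

    Cells are binned into `n_classes` equal age classes; the moment is
    the midpoint of the class with the largest mean FCplus.  Returns None
    when fewer than 10 cells have a defined FCplus or when every class
    mean is zero.
    """
    fc_values = np.asarray(fc_values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    ok = np.isfinite(fc_values)
    if ok.sum() < 10:
        return None
    fc, a = fc_values[ok], ages[ok]
    k = np.clip((a * n_classes).astype(int), 0, n_classes - 1)
    sums = np.bincount(k, weights=fc, minlength=n_classes)
    counts = np.bincount(k, minlength=n_classes)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if not np.any(np.nan_to_num(means) > 0):
        return None
    best = int(np.nanargmax(means))
    return (best + 0.5) / n_classes
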