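"""Place-field detection from ΔF/F traces on a linear track.

The 2 m track is divided into 40 position bins (5 cm each); frames
where the animal is immobile (speed below 1 cm/s) are excluded so that
spatial tuning is estimated during active exploration only.  A place
field is a contiguous run of bins whose trial-averaged ΔF/F exceeds the
cell's baseline by at least a 10% fluorescence change (0.10 ΔF/F),
accepted only if all four criteria hold:

1. mean in-field ΔF/F more than 10% (0.10 ΔF/F) above the cell's
   baseline (the 20th percentile of its 40-bin mean map);
2. significant calcium transients on strictly more than 30% of laps
   inside the field during running;
3. the rising flank of the spatial profile begins after the track start
   (the field is not truncated by the teleport boundary);
4. bootstrap p-value below 0.05, with a null built by independently
   circularly rotating each lap's bin vector.

Multiple candidate fields within one cell are treated independently.
Accepted fields carry the center of mass (activity-weighted position),
field width (25%-of-peak-above-baseline crossings, linearly
interpolated), lap-by-lap reliability and the out/in-field activity
ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .behavior import BehaviorSession, LapTable

__all__ = [
    "CalciumTraceSet",
    "SpatialActivityMap",
    "PlaceField",
    "BootstrapResult",
    "bin_activity",
    "detect_transients",
    "candidate_fields",
    "bootstrap_field_test",
    "field_criteria",
    "field_parameters",
    "detect_place_fields",
    "place_cell_fraction",
]

DEFAULT_N_BINS = 40
DEFAULT_SPEED_THRESHOLD = 1.0  # cm/s
DEFAULT_BASELINE_QUANTILE = 20.0  # percentile of the mean map
# criterion 1: "10% above the baseline" — ΔF/F is a percentage
# quantity, so the threshold is an absolute 0.10 ΔF/F above baseline
DEFAULT_MIN_DFF = 0.10
RELIABILITY_THRESHOLD = 0.30  # strict ">30% of laps"


@dataclass
class CalciumTraceSet:
    """ΔF/F traces (cells x frames) aligned to a behavior session."""

    dff: np.ndarray
    cell_ids: np.ndarray
    session: BehaviorSession

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        if self.dff.ndim != 2:
            raise ValueError("dff must be a 2-D cells x frames matrix")
        if self.dff.shape[1] != self.session.n_frames:
            raise ValueError(
                f"dff has {self.dff.shape[1]} frames but the behavior "
                f"session has {self.session.n_frames}"
            )
        if not np.all(np.isfinite(self.dff)):
            raise ValueError("dff contains non-finite values")
        self.cell_ids = np.asarray(self.cell_ids)
        if self.cell_ids.size != self.dff.shape[0]:
            raise ValueError("cell_ids length must equal the number of cells")

    @property
    def n_cells(self) -> int:
        return int(self.dff.shape[0])


@dataclass
class SpatialActivityMap:
    """Cells x laps x bins mean ΔF/F with per-lap occupancy counts.

    Entries are NaN where a (lap, bin) had no speed-included frames.
    """

    map: np.ndarray  # (cells, laps, bins), NaN where unobserved
    occupancy: np.ndarray  # (laps, bins) included-frame counts
    n_bins: int
    bin_width: float
    speed_threshold: float
    cell_ids: np.ndarray
    track_length: float

    def mean_profiles(self) -> np.ndarray:
        """Lap-averaged (cells x bins) profiles over observed laps."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.map, axis=1)

    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width


def position_bins(
    position: np.ndarray, track_length: float, n_bins: int
) -> np.ndarray:
    """0-based bin index; bins are half-open with the last bin closed."""
    bw = track_length / n_bins
    idx = np.floor(np.asarray(position, float) / bw).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def bin_activity(
    traces: CalciumTraceSet,
    laps: LapTable,
    n_bins: int = DEFAULT_N_BINS,
    speed_threshold: float = DEFAULT_SPEED_THRESHOLD,
) -> SpatialActivityMap:
    """Occupancy-normalised spatial activity map.

    Per cell, lap and bin: the mean ΔF/F over frames that belong to the
    lap, fall in the bin, and have ``|velocity| >= speed_threshold``.
    """
    if laps.n_laps == 0:
        raise ValueError("laps must be nonempty")
    ses = traces.session
    n_laps = laps.n_laps
    included = (laps.frame_lap >= 0) & (np.abs(ses.velocity) >= speed_threshold)
    bins = position_bins(ses.position, ses.track_length, n_bins)
    flat = laps.frame_lap[included] * n_bins + bins[included]
    size = n_laps * n_bins
    occupancy = np.bincount(flat, minlength=size).reshape(n_laps, n_bins)
    m = int(included.sum())
    if m:
        onehot = sparse.csr_matrix(
            (np.ones(m), (np.arange(m), flat)), shape=(m, size)
        )
        sums = np.asarray(traces.dff[:, included] @ onehot)
    else:
        sums = np.zeros((traces.n_cells, size))
    occ_flat = occupancy.reshape(-1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / occ_flat
    mean[:, occ_flat == 0] = np.nan
    return SpatialActivityMap(
        map=mean.reshape(traces.n_cells, n_laps, n_bins),
        occupancy=occupancy,
        n_bins=n_bins,
        bin_width=ses.track_length / n_bins,
        speed_threshold=speed_threshold,
        cell_ids=traces.cell_ids,
        track_length=ses.track_length,
    )


# ---------------------------------------------------------------------------
# transients
# ---------------------------------------------------------------------------

def detect_transients(
    traces: CalciumTraceSet,
    k_sigma: float = 2.0,
    sustain_sigma: float = 1.0,
    min_duration: float = 0.5,
    smooth_frames: int = 5,
) -> pd.DataFrame:
    """Significant calcium transients per cell.

    The trace is lightly smoothed (centered boxcar of ``smooth_frames``
    frames); a transient is a run of smoothed frames strictly above
    ``baseline + sustain_sigma * sigma`` that lasts at least
    ``min_duration`` seconds and contains at least one frame above the
    onset threshold ``baseline + k_sigma * sigma`` (onset/sustain
    hysteresis matching the indicator's fast-rise/slow-decay
    asymmetry).  Baseline is the per-cell median of the smoothed trace
    and sigma comes from its sub-baseline residuals mirrored about zero
    (transients only deflect upward, so the negative tail is noise).
    The reported ``onset`` is the first frame of the run where the
    *raw* trace sits above the onset threshold for two consecutive
    frames (sharper timing than the smoothed crossing, robust to a
    single early noise spike); ``offset`` is exclusive and
    ``peak_dff`` is the raw in-run maximum.
    """
    fr = traces.session.frame_rate
    min_frames = max(1, int(np.ceil(min_duration * fr - 1e-9)))
    if smooth_frames < 1:
        raise ValueError("smooth_frames must be >= 1")
    if sustain_sigma > k_sigma:
        raise ValueError("sustain_sigma must not exceed k_sigma")
    kernel = np.ones(smooth_frames) / smooth_frames
    rows = []
    for c in range(traces.n_cells):
        x = traces.dff[c]
        y = np.convolve(x, kernel, mode="same") if smooth_frames > 1 else x
        base = float(np.median(y))
        res = y - base
        neg = res[res < 0]
        sigma = float(np.sqrt(np.mean(neg**2))) if neg.size else 0.0
        high = res > k_sigma * sigma
        low = res > sustain_sigma * sigma
        padded = np.r_[False, low, False]
        d = np.diff(padded.astype(np.int8))
        starts = np.nonzero(d == 1)[0]
        stops = np.nonzero(d == -1)[0]
        raw_high = (x - base) > k_sigma * sigma
        raw_pair = raw_high & np.r_[raw_high[1:], False]
        for s, e in zip(starts, stops):
            if e - s < min_frames or not high[s:e].any():
                continue
            if raw_pair[s:e].any():
                onset = s + int(np.argmax(raw_pair[s:e]))
            elif raw_high[s:e].any():
                onset = s + int(np.argmax(raw_high[s:e]))
            else:
                onset = s
            rows.append(
                {
                    "cell": c,
                    "onset": int(onset),
                    "offset": int(e),
                    "peak_dff": float(x[s:e].max()),
                }
            )
    return pd.DataFrame(rows, columns=["cell", "onset", "offset", "peak_dff"])


# ---------------------------------------------------------------------------
# candidates and criteria
# ---------------------------------------------------------------------------

def _baseline(profile: np.ndarray, quantile: float) -> float:
    return float(np.nanpercentile(profile, quantile))


def candidate_fields(
    mean_profile: np.ndarray,
    baseline_quantile: float = DEFAULT_BASELINE_QUANTILE,
    min_dff: float = DEFAULT_MIN_DFF,
) -> list[tuple[int, int]]:
    """Maximal contiguous bin runs more than ``min_dff`` above baseline.

    Returns half-open ``(start, stop)`` bin ranges.  Unobserved (NaN)
    bins break runs, so no candidate spans an unobserved bin.
    """
    profile = np.asarray(mean_profile, dtype=float)
    if not np.any(np.isfinite(profile)):
        raise ValueError("mean profile has no observed bins")
    base = _baseline(profile, baseline_quantile)
    with np.errstate(invalid="ignore"):
        above = profile > base + min_dff
    above &= np.isfinite(profile)
    padded = np.r_[False, above, False]
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    stops = np.nonzero(d == -1)[0]
    return [(int(s), int(e)) for s, e in zip(starts, stops)]


@dataclass
class BootstrapResult:
    p: float
    observed: float
    n_shuffles: int


def bootstrap_field_test(
    cell_lap_maps: np.ndarray,
    candidate: tuple[int, int],
    n_shuffles: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> BootstrapResult:
    """Circular-rotation bootstrap for field significance.

    The statistic is mean in-candidate minus mean out-of-candidate
    ΔF/F.  The null is built by independently rotating each lap's bin
    vector by a uniform random offset, which preserves within-lap
    autocorrelation while destroying lap-consistent tuning.  The
    add-one estimator ``p = (1 + #{null >= observed}) / (1 + n)`` never
    returns 0.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    rng = np.random.default_rng(rng)
    maps = np.asarray(cell_lap_maps, dtype=float)
    n_laps, n_bins = maps.shape
    s, e = candidate
    in_mask = np.zeros(n_bins, dtype=bool)
    in_mask[s:e] = True
    out_mask = ~in_mask
    if not out_mask.any():
        raise ValueError("candidate spans all bins; statistic undefined")
    with np.errstate(invalid="ignore"):
        observed = float(
            np.nanmean(maps[:, in_mask]) - np.nanmean(maps[:, out_mask])
        )
    offsets = rng.integers(0, n_bins, size=(n_shuffles, n_laps))
    cols = (np.arange(n_bins)[None, None, :] - offsets[:, :, None]) % n_bins
    rolled = maps[np.arange(n_laps)[None, :, None], cols]  # (S, L, B)
    with np.errstate(invalid="ignore"):
        null = np.nanmean(rolled[:, :, in_mask], axis=(1, 2)) - np.nanmean(
            rolled[:, :, out_mask], axis=(1, 2)
        )
    p = (1.0 + int(np.sum(null >= observed))) / (1.0 + n_shuffles)
    return BootstrapResult(float(p), observed, n_shuffles)


@dataclass
class PlaceField:
    """One accepted place field with its descriptive parameters."""

    cell_id: object
    bin_start: int
    bin_stop: int  # exclusive
    com: float  # cm
    width: float  # cm
    reliability: float  # fraction of laps with an in-field transient onset
    out_in_ratio: float
    boot_p: float
    mean_infield_dff: float


@dataclass
class FieldDecision:
    """Outcome of the four-criterion test for one candidate."""

    accepted: bool
    reason: str | None  # first failed criterion, None when accepted
    reliability: float
    boot_p: float | None


def field_criteria(
    candidate: tuple[int, int],
    mean_profile: np.ndarray,
    cell_lap_maps: np.ndarray,
    onset_laps_bins: np.ndarray,
    n_laps: int,
    baseline_quantile: float = DEFAULT_BASELINE_QUANTILE,
    min_dff: float = DEFAULT_MIN_DFF,
    n_shuffles: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> FieldDecision:
    """Apply the four acceptance criteria to a candidate field.

    ``onset_laps_bins`` is an integer array of shape (n_onsets, 2)
    giving (lap, bin) of each running-frame transient onset of the
    cell.  Criteria are evaluated in order and the rejection carries
    the first failure; the bootstrap runs only when 1-3 pass.
    """
    s, e = candidate
    profile = np.asarray(mean_profile, dtype=float)
    base = _baseline(profile, baseline_quantile)
    observed = np.isfinite(profile)
    # criterion 1: mean in-field activity >0.10 ΔF/F above baseline, and
    # the candidate must leave some out-of-field track for the comparison
    if not np.nanmean(profile[s:e]) > base + min_dff:
        return FieldDecision(False, "criterion1_amplitude", np.nan, None)
    if np.count_nonzero(observed[s:e]) == np.count_nonzero(observed):
        return FieldDecision(False, "criterion1_no_out_of_field", np.nan, None)
    # criterion 2: transient onsets inside the field on >30% of laps
    if onset_laps_bins.size:
        in_field = (onset_laps_bins[:, 1] >= s) & (onset_laps_bins[:, 1] < e)
        reliability = np.unique(onset_laps_bins[in_field, 0]).size / n_laps
    else:
        reliability = 0.0
    if not reliability > RELIABILITY_THRESHOLD:
        return FieldDecision(False, "criterion2_reliability", reliability, None)
    # criterion 3: the rising flank begins on the track (field not
    # truncated at the teleport boundary)
    if s == 0:
        return FieldDecision(False, "criterion3_rising_phase", reliability, None)
    # criterion 4: bootstrap significance
    boot = bootstrap_field_test(cell_lap_maps, candidate, n_shuffles, rng)
    if not boot.p < alpha:
        return FieldDecision(False, "criterion4_bootstrap", reliability, boot.p)
    return FieldDecision(True, None, reliability, boot.p)


def field_parameters(
    candidate: tuple[int, int],
    mean_profile: np.ndarray,
    bin_width: float,
    baseline_quantile: float = DEFAULT_BASELINE_QUANTILE,
) -> tuple[float, float, float, float]:
    """(com, width, out_in_ratio, mean_infield) for an accepted candidate.

    COM is the activity-weighted mean of in-field bin centers.  Width is
    the contiguous extent around the in-field peak where the profile
    stays at or above baseline + 25% of (peak - baseline), with the
    crossing positions linearly interpolated between bin centers and
    clipped to the track; it is never reported below one bin width.
    """
    s, e = candidate
    profile = np.asarray(mean_profile, dtype=float)
    n_bins = profile.size
    centers = (np.arange(n_bins) + 0.5) * bin_width
    infield = profile[s:e]
    weights = infield.copy()
    weights[~np.isfinite(weights)] = 0.0
    total = weights.sum()
    com = float((centers[s:e] * weights).sum() / total) if total else float(
        centers[s:e].mean()
    )
    base = _baseline(profile, baseline_quantile)
    peak_rel = int(np.nanargmax(infield))
    peak = s + peak_rel
    level = base + 0.25 * (profile[peak] - base)

    def _cross(direction: int) -> float:
        i = peak
        while True:
            j = i + direction
            if j < 0 or j >= n_bins:
                return 0.0 if direction < 0 else n_bins * bin_width
            if not np.isfinite(profile[j]):
                # unobserved neighbour: the field cannot be traced past
                # it, so the crossing is placed at the bin edge
                return float(centers[i] + direction * 0.5 * bin_width)
            if profile[j] < level:
                # linear interpolation between bin centers i and j
                frac = (profile[i] - level) / (profile[i] - profile[j])
                return float(centers[i] + direction * frac * bin_width)
            i = j

    left = max(0.0, _cross(-1))
    right = min(n_bins * bin_width, _cross(+1))
    width = max(right - left, bin_width)
    out_mask = np.isfinite(profile)
    out_mask[s:e] = False
    out_vals = profile[out_mask]
    mean_in = float(np.nanmean(infield))
    out_in = float(np.mean(out_vals) / mean_in) if out_vals.size and mean_in else np.nan
    return com, float(width), out_in, mean_in


@dataclass
class PlaceFieldResult:
    """All accepted fields plus per-candidate rejection bookkeeping."""

    fields: pd.DataFrame
    rejections: pd.DataFrame
    n_cells: int

    def cells_with_fields(self) -> np.ndarray:
        if len(self.fields) == 0:
            return np.array([], dtype=object)
        return self.fields["cell_id"].unique()


def _onsets_to_laps_bins(
    transients: pd.DataFrame,
    traces: CalciumTraceSet,
    laps: LapTable,
    n_bins: int,
    speed_threshold: float,
) -> dict[int, np.ndarray]:
    """Map each cell's running-frame transient onsets to (lap, bin)."""
    ses = traces.session
    bins = position_bins(ses.position, ses.track_length, n_bins)
    running = np.abs(ses.velocity) >= speed_threshold
    per_cell: dict[int, np.ndarray] = {}
    for c, grp in transients.groupby("cell"):
        onsets = grp["onset"].to_numpy(int)
        ok = (laps.frame_lap[onsets] >= 0) & running[onsets]
        onsets = onsets[ok]
        per_cell[int(c)] = np.column_stack(
            [laps.frame_lap[onsets], bins[onsets]]
        ) if onsets.size else np.empty((0, 2), dtype=int)
    return per_cell


def detect_place_fields(
    traces: CalciumTraceSet,
    laps: LapTable,
    sam: SpatialActivityMap | None = None,
    transients: pd.DataFrame | None = None,
    n_bins: int = DEFAULT_N_BINS,
    speed_threshold: float = DEFAULT_SPEED_THRESHOLD,
    baseline_quantile: float = DEFAULT_BASELINE_QUANTILE,
    min_dff: float = DEFAULT_MIN_DFF,
    n_shuffles: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> PlaceFieldResult:
    """Run the full detection pipeline for every cell.

    The per-candidate bootstrap draws from one seeded generator, so the
    whole result is reproducible from ``seed``.
    """
    if sam is None:
        sam = bin_activity(traces, laps, n_bins, speed_threshold)
    if transients is None:
        transients = detect_transients(traces)
    rng = np.random.default_rng(seed)
    profiles = sam.mean_profiles()
    per_cell_onsets = _onsets_to_laps_bins(
        transients, traces, laps, sam.n_bins, sam.speed_threshold
    )
    empty = np.empty((0, 2), dtype=int)
    field_rows, rej_rows = [], []
    for c in range(traces.n_cells):
        profile = profiles[c]
        if not np.any(np.isfinite(profile)):
            continue
        for cand in candidate_fields(profile, baseline_quantile, min_dff):
            decision = field_criteria(
                cand,
                profile,
                sam.map[c],
                per_cell_onsets.get(c, empty),
                laps.n_laps,
                baseline_quantile,
                min_dff,
                n_shuffles,
                alpha,
                rng,
            )
            if not decision.accepted:
                rej_rows.append(
                    {
                        "cell_id": traces.cell_ids[c],
                        "bin_start": cand[0],
                        "bin_stop": cand[1],
                        "reason": decision.reason,
                    }
                )
                continue
            com, width, out_in, mean_in = field_parameters(
                cand, profile, sam.bin_width, baseline_quantile
            )
            field_rows.append(
                {
                    "cell_id": traces.cell_ids[c],
                    "bin_start": cand[0],
                    "bin_stop": cand[1],
                    "com": com,
                    "width": width,
                    "reliability": decision.reliability,
                    "out_in_ratio": out_in,
                    "boot_p": decision.boot_p,
                    "mean_infield_dff": mean_in,
                }
            )
    columns = [
        "cell_id", "bin_start", "bin_stop", "com", "width",
        "reliability", "out_in_ratio", "boot_p", "mean_infield_dff",
    ]
    fields = pd.DataFrame(field_rows, columns=columns)
    rejections = pd.DataFrame(
        rej_rows, columns=["cell_id", "bin_start", "bin_stop", "reason"]
    )
    return PlaceFieldResult(fields, rejections, traces.n_cells)


def place_cell_fraction(result: PlaceFieldResult) -> float:
    """Percent of recorded cells with at least one accepted field."""
    if result.n_cells == 0:
        return float("nan")
    return 100.0 * len(result.cells_with_fields()) / result.n_cells
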