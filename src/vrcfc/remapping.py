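"""Place-map stability within and across sessions.

Within-session stability is the split-half correlation: the Pearson
correlation between the mean 40-bin profile of the first half of laps
and that of the second half (the extra lap of an odd count goes to the
first half).  Across-session stability correlates the session-mean
profiles of matched cells, restricted — when a field table for the
reference session is supplied — to cells holding an accepted field
there, mirroring the "fields defined on day 0, tracked on day 1"
logic.  Bins unobserved in either profile are dropped pairwise; pairs
sharing fewer than 10 observed bins are undefined (NaN).

Population-level field-parameter changes (width, reliability, out/in
ratio, place-cell fraction) are compared at the mouse level — paired
tests across per-mouse means, avoiding pseudoreplication across cells —
with pooled-cell KS statistics retained as descriptive distribution
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .placecells import SpatialActivityMap

__all__ = [
    "split_half_correlation",
    "split_half_correlations",
    "across_session_correlation",
    "FieldPopulationComparison",
    "compare_field_populations",
]

MIN_COMMON_BINS = 10
MIN_LAPS = 4


def _profile_corr(
    x: np.ndarray, y: np.ndarray, method: str = "pearson"
) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < MIN_COMMON_BINS:
        return float("nan")
    x, y = x[ok], y[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    if method == "pearson":
        return float(sps.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(sps.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def split_half_correlation(
    sam: SpatialActivityMap, cell: int, method: str = "pearson"
) -> float:
    """First-half vs second-half lap-mean profile correlation for one cell."""
    lap_maps = sam.map[cell]
    n_laps = lap_maps.shape[0]
    if n_laps < MIN_LAPS:
        return float("nan")
    half = (n_laps + 1) // 2  # odd lap counts: extra lap to the first half
    with np.errstate(invalid="ignore"):
        first = np.nanmean(lap_maps[:half], axis=0)
        second = np.nanmean(lap_maps[half:], axis=0)
    return _profile_corr(first, second, method)


def split_half_correlations(
    sam: SpatialActivityMap, method: str = "pearson"
) -> np.ndarray:
    return np.array(
        [split_half_correlation(sam, c, method) for c in range(sam.map.shape[0])]
    )


def across_session_correlation(
    sam_a: SpatialActivityMap,
    sam_b: SpatialActivityMap,
    match: pd.DataFrame,
    fields_a: pd.DataFrame | None = None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Per-matched-cell correlation of session-mean spatial profiles.

    ``match`` has columns ``cell_id_a, cell_id_b``.  When ``fields_a``
    (an accepted-field table with ``cell_id``, ``bin_start``,
    ``bin_stop``, ``com``) is given, only reference-session field
    holders are analysed and the output also carries the field's COM in
    session A together with the COM of session B's profile over the
    same bins (the across-day COM pair).  Unmatched or filtered cells
    are skipped; the skip count is in ``df.attrs["n_skipped"]``.
    """
    ids_a = {cid: i for i, cid in enumerate(np.asarray(sam_a.cell_ids))}
    ids_b = {cid: i for i, cid in enumerate(np.asarray(sam_b.cell_ids))}
    prof_a = sam_a.mean_profiles()
    prof_b = sam_b.mean_profiles()
    centers = sam_a.bin_centers()
    field_lookup: dict[object, pd.DataFrame] = {}
    if fields_a is not None:
        field_lookup = {cid: grp for cid, grp in fields_a.groupby("cell_id")}
    rows = []
    skipped = 0
    for _, pair in match.iterrows():
        ca, cb = pair["cell_id_a"], pair["cell_id_b"]
        if ca not in ids_a or cb not in ids_b:
            skipped += 1
            continue
        if fields_a is not None and ca not in field_lookup:
            skipped += 1
            continue
        pa, pb = prof_a[ids_a[ca]], prof_b[ids_b[cb]]
        r = _profile_corr(pa, pb, method)
        row = {"cell_id_a": ca, "cell_id_b": cb, "r": r}
        if fields_a is not None:
            fld = field_lookup[ca].iloc[0]
            s, e = int(fld["bin_start"]), int(fld["bin_stop"])
            row["com_a"] = float(fld["com"])
            # COM of session B's activity over the reference field's
            # bins, weighted above B's baseline so the noise floor
            # outside the bump does not drag the estimate
            w = pb[s:e] - np.nanpercentile(pb, 20)
            w[~np.isfinite(w)] = 0.0
            w = np.clip(w, 0.0, None)
            row["com_b"] = (
                float((centers[s:e] * w).sum() / w.sum())
                if w.sum() > 0 else float("nan")
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["n_skipped"] = skipped
    return out


@dataclass
class FieldPopulationComparison:
    """Mouse-level paired comparison of field parameters across sessions.

    ``summary`` has one row per parameter with per-mouse paired means,
    the paired t statistic/p (NaN with a single mouse) and the
    pooled-cell two-sample KS statistic/p.  Direction flags mark a
    significant width decrease (``narrowing``) and a place-cell
    fraction increase.
    """

    summary: pd.DataFrame
    n_mice: int
    fraction_a: float
    fraction_b: float
    narrowing: bool
    fraction_increase: bool


def _mouse_means(fields: pd.DataFrame, param: str, mouse_col: str) -> pd.Series:
    return fields.groupby(mouse_col)[param].mean()


def compare_field_populations(
    fields_a: pd.DataFrame,
    fields_b: pd.DataFrame,
    n_cells_a: dict | int | None = None,
    n_cells_b: dict | int | None = None,
    params: tuple[str, ...] = ("width", "reliability", "out_in_ratio"),
    mouse_col: str = "mouse_id",
    alpha: float = 0.05,
) -> FieldPopulationComparison:
    """Compare field-parameter populations between two analysed sessions.

    ``fields_*`` are accepted-field tables; a ``mouse_id`` column
    enables mouse-level paired inference (without one, all fields are
    treated as a single mouse and the comparison is descriptive only).
    ``n_cells_*`` (total recorded cells, per mouse or pooled) enable the
    place-cell fraction comparison.
    """
    fa = fields_a.copy()
    fb = fields_b.copy()
    for f in (fa, fb):
        if mouse_col not in f.columns:
            f[mouse_col] = 0
    mice = sorted(set(fa[mouse_col]) & set(fb[mouse_col]))
    rows = []
    for param in params:
        ma = _mouse_means(fa, param, mouse_col).reindex(mice)
        mb = _mouse_means(fb, param, mouse_col).reindex(mice)
        ok = ma.notna() & mb.notna()
        a, b = ma[ok].to_numpy(), mb[ok].to_numpy()
        if a.size >= 2 and np.ptp(b - a) > 0:
            t, p = sps.ttest_rel(a, b)
        else:
            t, p = float("nan"), float("nan")
        xa = fa[param].dropna().to_numpy()
        xb = fb[param].dropna().to_numpy()
        if xa.size and xb.size:
            ks = sps.ks_2samp(xa, xb)
            ks_stat, ks_p = float(ks.statistic), float(ks.pvalue)
        else:
            ks_stat, ks_p = float("nan"), float("nan")
        rows.append(
            {
                "parameter": param,
                "n_mice": int(a.size),
                "mean_a": float(a.mean()) if a.size else float("nan"),
                "mean_b": float(b.mean()) if b.size else float("nan"),
                "delta": float((b - a).mean()) if a.size else float("nan"),
                "t": float(t),
                "p": float(p),
                "ks_stat": ks_stat,
                "ks_p": ks_p,
            }
        )
    summary = pd.DataFrame(rows)

    def _fraction(fields: pd.DataFrame, n_cells) -> float:
        if n_cells is None:
            return float("nan")
        total = sum(n_cells.values()) if isinstance(n_cells, dict) else n_cells
        return 100.0 * fields["cell_id"].nunique() / total if total else float("nan")

    frac_a = _fraction(fa, n_cells_a)
    frac_b = _fraction(fb, n_cells_b)
    width_row = summary.loc[summary["parameter"] == "width"]
    narrowing = bool(
        len(width_row)
        and width_row["delta"].iloc[0] < 0
        and width_row["p"].iloc[0] < alpha
    )
    fraction_increase = bool(
        np.isfinite(frac_a) and np.isfinite(frac_b) and frac_b > frac_a
    )
    return FieldPopulationComparison(
        summary, len(mice), frac_a, frac_b, narrowing, fraction_increase
    )
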