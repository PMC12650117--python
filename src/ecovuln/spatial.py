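"""Spatial analysis: stable-ecosystem masking, sampling, gradients, ANOVA.

Post-assessment statistics over the index surfaces:

* the stable-ecosystem mask (pixels whose land-cover class never
  changes over the study years), isolating climate-driven signals from
  land-use change;
* multi-year means of the midpoint-year index stacks;
* systematic grid-based point sampling for ecosystem comparisons;
* binned zonal profiles (1° latitude/longitude, 100 m elevation by
  convention) with linear or piecewise gradient fits;
* one-way ANOVA with Tukey–Kramer pairwise comparisons and a compact
  letter display across ecosystem classes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import IndexSeries
from .synthetic import LANDCOVER_CLASSES, LandcoverMaps

__all__ = [
    "BinnedProfile",
    "EcosystemSample",
    "stable_ecosystem_mask",
    "multi_year_mean",
    "systematic_sample",
    "bin_profile",
    "fit_gradient",
    "ecosystem_anova",
    "compact_letter_display",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# stable-ecosystem mask
# ---------------------------------------------------------------------------

def stable_ecosystem_mask(landcover: LandcoverMaps
                          ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Pixels whose ecosystem class is identical in every provided year.

    A pixel is stable iff its class never changes across the annual maps
    and that class is one of the five ecosystem classes (nodata
    excluded). Returns the overall mask and one mask per class.
    """
    maps = landcover.maps
    if maps.ndim != 3 or maps.shape[0] < 2:
        raise ValueError("need at least 2 annual land-cover maps")
    same = (maps == maps[0]).all(axis=0)
    stable = same & (maps[0] > 0)
    per_class = {name: stable & (maps[0] == code + 1)
                 for code, name in enumerate(LANDCOVER_CLASSES)}
    return stable, per_class


# ---------------------------------------------------------------------------
# multi-year mean
# ---------------------------------------------------------------------------

def multi_year_mean(series: IndexSeries, index: str = "VI", *,
                    min_valid_fraction: float = 0.5) -> np.ndarray:
    """Temporal mean surface of an index, ignoring nodata.

    Pixels valid in fewer than ``min_valid_fraction`` of the windows are
    masked.
    """
    stack = series[index]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
    frac = np.isfinite(stack).mean(axis=0)
    mean[frac < min_valid_fraction] = np.nan
    return mean


# ---------------------------------------------------------------------------
# systematic sampling
# ---------------------------------------------------------------------------

@dataclass
class EcosystemSample:
    """One sampled point: location, ecosystem class, multi-year mean indices."""

    row: int
    col: int
    lat: float
    lon: float
    ecosystem: str
    values: dict[str, float]


def systematic_sample(mask: np.ndarray, n_points: int,
                      seed: int = 0) -> list[tuple[int, int]]:
    """Regular-lattice point sample over the valid pixels of a mask.

    The lattice spacing is sized so that roughly ``n_points`` lattice
    nodes fall on valid pixels; the lattice offset is drawn from the
    seed, so repeated calls with one seed return identical points. If
    ``n_points`` meets or exceeds the number of valid pixels, every
    valid pixel is returned with a warning.
    """
    if not mask.any():
        raise ValueError("empty mask")
    valid_idx = np.argwhere(mask)
    n_valid = len(valid_idx)
    if n_points >= n_valid:
        if n_points > n_valid:
            warnings.warn(f"requested {n_points} points but only {n_valid} "
                          "valid pixels; returning all of them", stacklevel=2)
        return [tuple(rc) for rc in valid_idx]
    # spacing from the valid-pixel density so ~n_points nodes hit the mask;
    # pick the integer spacing whose expected hit count is closest to n
    s_real = np.sqrt(n_valid / n_points)
    cands = {max(int(np.floor(s_real)), 1), max(int(np.ceil(s_real)), 1)}
    spacing = min(cands, key=lambda s: abs(n_valid / s**2 - n_points))
    rng = np.random.default_rng(seed)
    r0, c0 = rng.integers(0, spacing, size=2)
    rows = np.arange(r0, mask.shape[0], spacing)
    cols = np.arange(c0, mask.shape[1], spacing)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    on = mask[rr, cc]
    return list(zip(rr[on].tolist(), cc[on].tolist()))


def sample_ecosystems(series: IndexSeries, landcover: LandcoverMaps,
                      n_points: int, seed: int = 0) -> list[EcosystemSample]:
    """Systematic ecosystem samples carrying multi-year mean index values."""
    stable, _ = stable_ecosystem_mask(landcover)
    means = {k: multi_year_mean(series, k) for k in ("EI", "SI", "RI", "VI")}
    valid = stable & np.isfinite(means["VI"])
    pts = systematic_sample(valid, n_points, seed)
    lats, lons = series.grid.lats, series.grid.lons
    base = landcover.maps[0]
    out = []
    for r, c in pts:
        out.append(EcosystemSample(
            row=r, col=c, lat=float(lats[r]), lon=float(lons[c]),
            ecosystem=LANDCOVER_CLASSES[base[r, c] - 1],
            values={k: float(means[k][r, c]) for k in means}))
    return out


# ---------------------------------------------------------------------------
# binned profiles and gradient fits
# ---------------------------------------------------------------------------

@dataclass
class BinnedProfile:
    """Mean of an index surface within contiguous coordinate bins."""

    bin_edges: np.ndarray
    bin_means: np.ndarray
    bin_counts: np.ndarray
    variable: str
    index: str

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def occupied(self) -> tuple[np.ndarray, np.ndarray]:
        """(centers, means) of bins with at least one valid pixel."""
        has = self.bin_counts > 0
        return self.bin_centers[has], self.bin_means[has]


def bin_profile(surface: np.ndarray, coordinate_raster: np.ndarray,
                bin_width: float, *, variable: str = "latitude",
                index: str = "VI") -> BinnedProfile:
    """Aggregate a surface into fixed-width coordinate bins.

    Bin edges are multiples of ``bin_width`` spanning the coordinate
    range (e.g. whole degrees for 1° bins); each bin's value is the mean
    of the valid surface pixels whose coordinate falls in it.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if surface.shape != coordinate_raster.shape:
        raise ValueError("surface and coordinate raster must be aligned")
    ok = np.isfinite(surface) & np.isfinite(coordinate_raster)
    coords = coordinate_raster[ok]
    vals = surface[ok]
    # floor convention: a value v belongs to [k*w, (k+1)*w) exactly
    k = np.floor(coords / bin_width).astype(np.int64)
    k0, k1 = int(k.min()), int(k.max())
    edges = np.arange(k0, k1 + 2) * bin_width
    which = k - k0
    counts = np.bincount(which, minlength=len(edges) - 1)
    sums = np.bincount(which, weights=vals, minlength=len(edges) - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return BinnedProfile(edges, means, counts, variable, index)


@dataclass
class GradientFit:
    model: str                   # "linear" or "piecewise"
    slopes: list[float]
    breakpoint: float | None
    r_squared: float
    p_value: float


def fit_gradient(profile: BinnedProfile, model: str = "linear", *,
                 weighted: bool = False) -> GradientFit:
    """Regression of binned means on the bin-centre coordinate.

    Linear mode is plain OLS on the occupied bins (unweighted by
    default; ``weighted=True`` weights by bin counts). Piecewise mode
    fits one breakpoint with the shared continuous segmented-regression
    routine and reports both segment slopes.
    """
    x, y = profile.occupied()
    if model == "linear":
        if len(x) < 3:
            raise ValueError("need at least 3 occupied bins")
        if weighted:
            w = profile.bin_counts[profile.bin_counts > 0].astype(float)
            coef = np.polyfit(x, y, 1, w=np.sqrt(w))
            yhat = np.polyval(coef, x)
            ybar = np.average(y, weights=w)
            r2 = 1 - np.average((y - yhat) ** 2, weights=w) / \
                np.average((y - ybar) ** 2, weights=w)
            # p-value from the unweighted fit, reported for reference
            p = stats.linregress(x, y).pvalue
            return GradientFit("linear", [float(coef[0])], None, float(r2),
                               float(p))
        res = stats.linregress(x, y)
        return GradientFit("linear", [float(res.slope)], None,
                           float(res.rvalue ** 2), float(res.pvalue))
    if model == "piecewise":
        if len(x) < 5:
            raise ValueError("need at least 5 occupied bins for piecewise")
        from .temporal import detect_phases
        seg = detect_phases(x, y, max_breaks=1, min_segment=0, n_breaks=1)
        resid = y - seg.fitted
        tot = y - y.mean()
        r2 = 1 - float(resid @ resid) / float(tot @ tot) if (tot @ tot) else 1.0
        p = min((ph["p"] for ph in seg.phases if np.isfinite(ph["p"])),
                default=np.nan)
        return GradientFit("piecewise", [ph["slope"] for ph in seg.phases],
                           float(seg.breakpoints[0]), r2, float(p))
    raise ValueError(f"unknown gradient model {model!r}")


# ---------------------------------------------------------------------------
# ecosystem ANOVA
# ---------------------------------------------------------------------------

def compact_letter_display(classes: list[str], means: dict[str, float],
                           distinct: set[tuple[str, str]]) -> dict[str, str]:
    """Assign significance letters by insert-and-absorb.

    Classes sharing a letter are not significantly different. Starting
    from one group holding every class, each significantly different
    pair splits the groups that contain both members; duplicate and
    fully contained groups are then absorbed. Letters are ordered by
    descending group mean (ties broken by name).
    """
    groups: list[set[str]] = [set(classes)]
    for i, j in sorted(distinct):
        nxt: list[set[str]] = []
        for g in groups:
            if i in g and j in g:
                nxt.append(g - {i})
                nxt.append(g - {j})
            else:
                nxt.append(g)
        groups = nxt
    # absorb: drop duplicates and groups contained in another
    uniq: list[set[str]] = []
    for g in groups:
        if g and not any(g <= h for h in uniq) :
            uniq = [h for h in uniq if not h < g]
            uniq.append(g)
    uniq.sort(key=lambda g: (-max(means[c] for c in g), sorted(g)))
    letters = {c: "" for c in classes}
    for i, g in enumerate(uniq):
        for c in g:
            letters[c] += chr(ord("a") + i)
    return {c: "".join(sorted(v)) for c, v in letters.items()}


@dataclass
class AnovaResult:
    index: str
    f_statistic: float
    p_value: float
    class_means: dict[str, float]
    letters: dict[str, str]
    tukey_table: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        rows = [{"class": c, "index": self.index, "mean": m,
                 "letter": self.letters[c]}
                for c, m in self.class_means.items()]
        return pd.DataFrame(rows)


def ecosystem_anova(samples: list[EcosystemSample], index: str = "VI", *,
                    alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA with Tukey–Kramer pairwise comparisons across classes.

    Classes with fewer than 2 samples are dropped with a warning. The
    honest-significant-difference test uses the Kramer adjustment for
    unequal group sizes; the compact letter display marks classes whose
    means are statistically indistinguishable at ``alpha``.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = pd.DataFrame({"class": [s.ecosystem for s in samples],
                       "value": [s.values[index] for s in samples]})
    df = df[np.isfinite(df["value"])]
    sizes = df.groupby("class").size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"dropping classes with <2 samples: {small}",
                      stacklevel=2)
        df = df[~df["class"].isin(small)]
    classes = sorted(df["class"].unique())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes with >=2 samples each")
    groups = [df.loc[df["class"] == c, "value"].to_numpy() for c in classes]
    f_stat, p_val = stats.f_oneway(*groups)

    tk = pairwise_tukeyhsd(df["value"].to_numpy(), df["class"].to_numpy(),
                           alpha=alpha)
    table = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    distinct = {(min(a, b), max(a, b))
                for a, b, rej in zip(table["group1"], table["group2"],
                                     table["reject"]) if rej}
    means = {c: float(g.mean()) for c, g in zip(classes, groups)}
    letters = compact_letter_display(classes, means, distinct)
    return AnovaResult(index, float(f_stat), float(p_val), means, letters,
                       table)
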