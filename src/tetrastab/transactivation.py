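"""Reporter-assay quantification: OD normalization, empty-vector
background subtraction, per-allele aggregation, fold-changes versus WT,
and Dunnett many-to-one comparisons.

The measurement model of a yeast luciferase transactivation assay is
multiplicative in culture density: raw luminescence scales with the
optical density (OD600) of the culture, on top of a p53-independent
background expression of the reporter.  Quantification therefore
proceeds as

1. normalize: RLU = luminescence / OD600 per well;
2. subtract the mean normalized signal of matched empty-vector wells
   (same reporter strain, same galactose dose) — negatives are kept,
   not clipped, since clipping would bias means near background;
3. aggregate per allele/strain/dose: mean net RLU, t-based confidence
   interval, and fold-change against WT at the same strain/dose;
4. compare each allele to the WT control with Dunnett's many-to-one
   procedure (family-wise error control), reporting the conventional
   significance stars.

The module exposes both plain functions and a statsmodels-style
``TransactivationModel.from_dataframe(...).fit()`` returning a
:class:`TransactivationResults` with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import MissingControlError, SampleSizeError

REQUIRED_COLUMNS = (
    "allele",
    "reporter_strain",
    "galactose_pct",
    "transformant_id",
    "luminescence",
    "od600",
)

#: Allele label identifying empty-vector control wells.
EMPTY_ALLELE = "EMPTY"

_STAR_TIERS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_stars(p: float) -> str:
    """Conventional star notation: **** p<1e-4 ... * p<0.05, else ns."""
    for cut, stars in _STAR_TIERS:
        if p < cut:
            return stars
    return "ns"


def validate_plate(plate: pd.DataFrame) -> pd.DataFrame:
    """Check the plate table's columns and domains; returns the frame."""
    missing = [c for c in REQUIRED_COLUMNS if c not in plate.columns]
    if missing:
        raise ValueError(f"plate table lacks columns: {missing}")
    if (plate["od600"] <= 0).any():
        bad = plate.index[plate["od600"] <= 0].tolist()[:5]
        raise ValueError(f"od600 must be positive; offending rows {bad}")
    if (plate["luminescence"] < 0).any():
        raise ValueError("luminescence must be nonnegative")
    if (plate["galactose_pct"] < 0).any():
        raise ValueError("galactose_pct must be nonnegative")
    return plate


def normalize_luminescence(luminescence, od600):
    """RLU per OD: luminescence / od600 (vectorized).

    Raises ``ValueError`` identifying the wells with nonpositive OD.
    """
    lum = np.asarray(luminescence, dtype=np.float64)
    od = np.asarray(od600, dtype=np.float64)
    if np.any(od <= 0):
        bad = np.nonzero(od <= 0)[0].tolist()
        raise ValueError(f"od600 must be positive; offending well index(es): {bad}")
    return lum / od


def subtract_background(values, empty_values):
    """Net values: each value minus the mean of the matched empty-vector
    wells.  Negatives are retained.

    Raises :class:`MissingControlError` when no empty wells are supplied.
    """
    empty = np.asarray(empty_values, dtype=np.float64)
    if empty.size == 0:
        raise MissingControlError("no matching empty-vector wells to estimate background")
    return np.asarray(values, dtype=np.float64) - float(empty.mean())


def net_values_table(plate: pd.DataFrame) -> pd.DataFrame:
    """Per-well OD-normalized, background-subtracted values.

    Adds columns ``rlu`` (normalized) and ``net_rlu``; background is the
    mean normalized empty-vector signal per (strain, dose).  Empty-vector
    rows are dropped from the output (their expected net is 0).
    """
    plate = validate_plate(plate).copy()
    plate["rlu"] = normalize_luminescence(plate["luminescence"], plate["od600"])

    out = []
    for (strain, dose), grp in plate.groupby(["reporter_strain", "galactose_pct"], sort=False):
        empty = grp.loc[grp["allele"] == EMPTY_ALLELE, "rlu"]
        if empty.empty:
            raise MissingControlError(
                f"no empty-vector wells for reporter strain {strain!r} at "
                f"galactose {dose}%"
            )
        rest = grp[grp["allele"] != EMPTY_ALLELE].copy()
        rest["net_rlu"] = subtract_background(rest["rlu"].to_numpy(), empty.to_numpy())
        out.append(rest)
    result = pd.concat(out, ignore_index=True)
    result["below_background"] = result["net_rlu"] < 0
    return result


@dataclass(frozen=True)
class TransactivationResult:
    """Aggregated activity of one allele at one strain/dose."""

    allele: str
    strain: str
    dose: float
    n: int
    mean_net_rlu: float
    ci_halfwidth: float | None
    fold_vs_wt: float


def aggregate_allele(
    net: pd.DataFrame,
    wt_allele: str = "WT",
    ci_level: float = 0.95,
) -> list[TransactivationResult]:
    """Mean net RLU, t-based CI halfwidth and fold-vs-WT per
    allele/strain/dose.

    The CI is reported only for n >= 2; fold requires WT at the same
    (strain, dose) — its absence is a :class:`MissingControlError`.
    """
    results: list[TransactivationResult] = []
    for (strain, dose), grp in net.groupby(["reporter_strain", "galactose_pct"], sort=False):
        wt_vals = grp.loc[grp["allele"] == wt_allele, "net_rlu"]
        if wt_vals.empty:
            raise MissingControlError(
                f"reference allele {wt_allele!r} absent at strain {strain!r}, "
                f"galactose {dose}%"
            )
        wt_mean = float(wt_vals.mean())
        for allele, avals in grp.groupby("allele", sort=False):
            vals = avals["net_rlu"].to_numpy()
            n = vals.size
            mean = float(vals.mean())
            if n >= 2:
                tcrit = float(stats.t.ppf(0.5 + ci_level / 2.0, df=n - 1))
                half = tcrit * float(vals.std(ddof=1)) / np.sqrt(n)
            else:
                half = None
            fold = mean / wt_mean if wt_mean != 0 else np.nan
            results.append(
                TransactivationResult(
                    allele=str(allele),
                    strain=str(strain),
                    dose=float(dose),
                    n=int(n),
                    mean_net_rlu=mean,
                    ci_halfwidth=half,
                    fold_vs_wt=float(fold),
                )
            )
    return results


@dataclass(frozen=True)
class DunnettComparison:
    """One allele-vs-control comparison with family-wise adjusted p."""

    allele: str
    effect: float
    p_adj: float
    stars: str


def compare_to_control(
    groups: dict[str, np.ndarray],
    control: np.ndarray,
    control_name: str = "WT",
    seed: int = 0,
) -> list[DunnettComparison]:
    """Dunnett's many-to-one comparisons of *groups* against *control*.

    Pooled within-group variance and the many-to-one multivariate-t
    reference distribution control the family-wise error across the
    comparisons.  With a single treatment group the procedure reduces
    exactly to the two-sided two-sample pooled-variance t-test, and that
    closed form is used.  For two or more groups the multivariate-t
    quantile is evaluated by scipy's quasi-Monte-Carlo integration with a
    seed derived from *seed*, so results are reproducible.

    Every group (and the control) must have n >= 2.
    """
    if not groups:
        raise SampleSizeError("need at least one treatment group")
    control = np.asarray(control, dtype=np.float64)
    if control.size < 2:
        raise SampleSizeError(f"control group {control_name!r} has n={control.size} < 2")
    names = list(groups)
    samples = [np.asarray(groups[k], dtype=np.float64) for k in names]
    for name, s in zip(names, samples):
        if s.size < 2:
            raise SampleSizeError(f"group {name!r} has n={s.size} < 2")

    effects = [float(s.mean() - control.mean()) for s in samples]

    if len(samples) == 1:
        s = samples[0]
        n1, n0 = s.size, control.size
        df = n1 + n0 - 2
        sp2 = ((n1 - 1) * s.var(ddof=1) + (n0 - 1) * control.var(ddof=1)) / df
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
        if se == 0:
            p = 1.0 if effects[0] == 0 else 0.0
        else:
            tstat = effects[0] / se
            p = float(2.0 * stats.t.sf(abs(tstat), df))
        pvals = [p]
    else:
        rng = np.random.default_rng(seed)
        res = stats.dunnett(*samples, control=control, random_state=rng)
        pvals = [float(p) for p in res.pvalue]

    return [
        DunnettComparison(allele=name, effect=eff, p_adj=p, stars=significance_stars(p))
        for name, eff, p in zip(names, effects, pvals)
    ]


# ---------------------------------------------------------------------------
# statsmodels-style surface


class TransactivationModel:
    """Reporter-assay analysis as a fit-able model.

    Parameters
    ----------
    plate
        Raw plate table (wells x readings), columns as in
        :data:`REQUIRED_COLUMNS`, including EMPTY rows per strain/dose.
    control
        Allele treated as the WT reference for folds and Dunnett tests.
    ci_level
        Confidence level of the per-group t intervals.
    """

    def __init__(self, plate: pd.DataFrame, control: str = "WT", ci_level: float = 0.95):
        self.plate = validate_plate(plate)
        self.control = control
        self.ci_level = ci_level

    @classmethod
    def from_dataframe(cls, plate: pd.DataFrame, control: str = "WT", **kw) -> "TransactivationModel":
        return cls(plate, control=control, **kw)

    @classmethod
    def from_tsv(cls, path, control: str = "WT", **kw) -> "TransactivationModel":
        return cls(pd.read_csv(path, sep="\t"), control=control, **kw)

    def fit(self, seed: int = 0) -> "TransactivationResults":
        net = net_values_table(self.plate)
        aggregated = aggregate_allele(net, wt_allele=self.control, ci_level=self.ci_level)

        comparisons: dict[tuple[str, float], list[DunnettComparison]] = {}
        for (strain, dose), grp in net.groupby(["reporter_strain", "galactose_pct"], sort=False):
            control_vals = grp.loc[grp["allele"] == self.control, "net_rlu"].to_numpy()
            others = {
                str(a): g["net_rlu"].to_numpy()
                for a, g in grp.groupby("allele", sort=False)
                if a != self.control
            }
            if others and control_vals.size >= 2 and all(v.size >= 2 for v in others.values()):
                comparisons[(str(strain), float(dose))] = compare_to_control(
                    others, control_vals, control_name=self.control, seed=seed
                )
        return TransactivationResults(self, net, aggregated, comparisons)


class TransactivationResults:
    """Fitted reporter-assay results: per-group estimates, intervals,
    folds, Dunnett comparisons, and a combined summary table."""

    def __init__(self, model, net, aggregated, comparisons):
        self.model = model
        self.net_values = net
        self.aggregated = aggregated
        self.comparisons = comparisons

    def summary(self) -> pd.DataFrame:
        """One row per allele/strain/dose: n, mean net RLU, CI halfwidth,
        fold vs control, adjusted p and stars (NaN/'' for the control)."""
        padj: dict[tuple[str, str, float], tuple[float, str]] = {}
        for (strain, dose), comps in self.comparisons.items():
            for c in comps:
                padj[(c.allele, strain, dose)] = (c.p_adj, c.stars)
        rows = []
        for r in self.aggregated:
            p, stars = padj.get((r.allele, r.strain, r.dose), (np.nan, ""))
            rows.append(
                {
                    "allele": r.allele,
                    "strain": r.strain,
                    "galactose_pct": r.dose,
                    "n": r.n,
                    "mean_net_rlu": r.mean_net_rlu,
                    "ci95_halfwidth": r.ci_halfwidth,
                    "fold_vs_wt": r.fold_vs_wt,
                    "p_adj": p,
                    "stars": stars,
                }
            )
        return pd.DataFrame(rows)

    def __repr__(self) -> str:
        n_groups = len(self.aggregated)
        return f"<TransactivationResults: {n_groups} allele/strain/dose groups>"
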