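"""Group statistics: mixed-design ANOVA, simple main effects,
Holm-Bonferroni pairwise comparisons, change correlations and t-tests.

The workhorse is a two-way mixed-design ANOVA with one between-subjects
factor (group: sauna vs control) and one within-subjects factor (sauna
set / stage).  For a balanced complete design with ``G`` groups of ``n``
participants each and ``A`` within levels the sums of squares decompose
as

    SS_total = SS_group + SS_subj(group)            (between subjects)
             + SS_within + SS_interaction + SS_error (within subjects)

with F ratios using the between-subjects error for the group effect and
the subject-by-within error ("MSe") for the within and interaction
effects.  Simple main effects of the within factor inside each group are
tested against the pooled within error term, and Holm-Bonferroni
pairwise comparisons of within levels use the same pooled MSe, matching
the reporting convention of mixed repeated-measures designs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import STAGES
from .errors import InsufficientDataError, ParameterError
from .spectral import BANDS

ALPHA = 0.05
MARGINAL_ALPHA = 0.1  # reported with its own flag ("+" convention)


def _f_and_p(ss_effect, df_effect, ms_error, df_error):
    """F ratio with degenerate-variance guards (0/0 -> F=0, p=1)."""
    ms_effect = ss_effect / df_effect
    if ms_error <= 0:
        if ms_effect <= 1e-12:
            return 0.0, 1.0
        return np.inf, 0.0
    f = ms_effect / ms_error
    return float(f), float(sps.f.sf(f, df_effect, df_error))


@dataclass
class MixedAnovaResult:
    """Result of :func:`mixed_anova`.

    ``table`` has one row per effect (group, within, interaction) with
    sums of squares, degrees of freedom, F and p.  ``ms_error_within`` is
    the pooled subject-by-within error mean square used by post-hoc
    comparisons.
    """

    table: pd.DataFrame
    ms_error_within: float
    df_error_within: int
    ms_error_between: float
    df_error_between: int
    groups: tuple
    levels: tuple
    n_per_group: int
    cell_means: pd.DataFrame  # index group, columns level
    _group_arrays: dict = field(repr=False, default_factory=dict)

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("effect").loc[name]

    def p(self, name: str) -> float:
        return float(self.effect(name)["p"])

    def f(self, name: str) -> float:
        return float(self.effect(name)["F"])

    def summary(self) -> pd.DataFrame:
        """Effect table with significance flags (* p<.05, + p<.1)."""
        out = self.table.copy()
        out["sig"] = np.where(out["p"] < ALPHA, "*",
                              np.where(out["p"] < MARGINAL_ALPHA, "+", ""))
        return out


def mixed_anova(df: pd.DataFrame, value: str = "value",
                participant: str = "participant", group: str = "group",
                within: str = "level") -> MixedAnovaResult:
    """Two-way mixed-design ANOVA on a tidy long table.

    Requires a balanced complete design: every participant measured at
    every within level, equal numbers of participants per group.
    Missing cells raise a typed error (no imputation).
    """
    for col in (value, participant, group, within):
        if col not in df.columns:
            raise ParameterError(f"column {col!r} not in data")
    pivot = df.pivot_table(index=[group, participant], columns=within,
                           values=value, aggfunc="mean")
    if pivot.isna().any().any():
        missing = int(pivot.isna().sum().sum())
        raise ParameterError(f"missing cells: {missing} participant-level "
                             "combinations absent (no imputation performed)")
    levels = tuple(pivot.columns)
    if set(levels) <= set(STAGES):  # present stages in study order
        levels = tuple(s for s in STAGES if s in levels)
        pivot = pivot[list(levels)]
    groups = tuple(sorted(pivot.index.get_level_values(0).unique()))
    if len(groups) < 2:
        raise ParameterError("need at least two groups")
    if len(levels) < 2:
        raise ParameterError("nothing to test: fewer than two within levels")
    arrays = {g: pivot.loc[g].to_numpy(dtype=float) for g in groups}
    ns = {g: a.shape[0] for g, a in arrays.items()}
    if len(set(ns.values())) != 1:
        raise ParameterError(f"unbalanced groups: {ns}")
    n = ns[groups[0]]
    if n < 2:
        raise InsufficientDataError(
            f"insufficient replication: {n} participant(s) per group"
        )
    G, A = len(groups), len(levels)
    Y = np.stack([arrays[g] for g in groups])  # (G, n, A)

    grand = Y.mean()
    subj_means = Y.mean(axis=2)           # (G, n)
    group_means = Y.mean(axis=(1, 2))     # (G,)
    level_means = Y.mean(axis=(0, 1))     # (A,)
    cell_means = Y.mean(axis=1)           # (G, A)

    ss_between_subj = A * np.sum((subj_means - grand) ** 2)
    ss_group = n * A * np.sum((group_means - grand) ** 2)
    ss_subj_err = max(ss_between_subj - ss_group, 0.0)

    ss_within_total = np.sum((Y - subj_means[:, :, None]) ** 2)
    ss_level = G * n * np.sum((level_means - grand) ** 2)
    ss_inter = n * np.sum(
        (cell_means - group_means[:, None] - level_means[None, :] + grand) ** 2
    )
    ss_err = max(ss_within_total - ss_level - ss_inter, 0.0)

    df_group, df_subj = G - 1, G * (n - 1)
    df_level = A - 1
    df_inter = (G - 1) * (A - 1)
    df_err = G * (n - 1) * (A - 1)

    ms_subj = ss_subj_err / df_subj
    ms_err = ss_err / df_err

    f_g, p_g = _f_and_p(ss_group, df_group, ms_subj, df_subj)
    f_w, p_w = _f_and_p(ss_level, df_level, ms_err, df_err)
    f_i, p_i = _f_and_p(ss_inter, df_inter, ms_err, df_err)

    table = pd.DataFrame([
        {"effect": "group", "ss": ss_group, "df1": df_group, "df2": df_subj,
         "F": f_g, "p": p_g},
        {"effect": "within", "ss": ss_level, "df1": df_level, "df2": df_err,
         "F": f_w, "p": p_w},
        {"effect": "interaction", "ss": ss_inter, "df1": df_inter,
         "df2": df_err, "F": f_i, "p": p_i},
    ])
    return MixedAnovaResult(
        table=table,
        ms_error_within=float(ms_err), df_error_within=df_err,
        ms_error_between=float(ms_subj), df_error_between=df_subj,
        groups=groups, levels=levels, n_per_group=n,
        cell_means=pd.DataFrame(cell_means, index=list(groups),
                                columns=list(levels)),
        _group_arrays=arrays,
    )


def simple_main_effects(result: MixedAnovaResult) -> pd.DataFrame:
    """Within-factor effect tested separately per group.

    Each group's within-level variation is tested against the *pooled*
    within error term from the omnibus ANOVA.
    """
    if len(result.levels) < 2:
        raise ParameterError("nothing to test: fewer than two within levels")
    A = len(result.levels)
    n = result.n_per_group
    rows = []
    for g in result.groups:
        cm = result.cell_means.loc[g].to_numpy(dtype=float)
        ss = n * np.sum((cm - cm.mean()) ** 2)
        f, p = _f_and_p(ss, A - 1, result.ms_error_within,
                        result.df_error_within)
        rows.append({"group": g, "F": f, "df1": A - 1,
                     "df2": result.df_error_within, "p": p,
                     "significant": p < ALPHA})
    return pd.DataFrame(rows)


def holm_adjust(p_raw) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, never below raw)."""
    p = np.asarray(p_raw, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def holm_pairwise(level_means, ms_error: float, n: int, df_error: int,
                  alpha: float = ALPHA) -> pd.DataFrame:
    """All pairwise within-level comparisons with Holm-adjusted p-values.

    ``level_means`` maps level -> mean (of ``n`` participants); each pair
    is tested with ``t = (m_a - m_b) / sqrt(2 * MSe / n)`` on the pooled
    error degrees of freedom.
    """
    if isinstance(level_means, pd.Series):
        level_means = level_means.to_dict()
    levels = list(level_means)
    if len(levels) < 2:
        raise ParameterError("nothing to compare: fewer than two levels")
    if n < 2:
        raise InsufficientDataError("insufficient replication for pairwise tests")
    se = np.sqrt(2.0 * ms_error / n)
    rows = []
    for a, b in itertools.combinations(levels, 2):
        diff = level_means[a] - level_means[b]
        if se == 0:
            t, p = (0.0, 1.0) if diff == 0 else (np.inf * np.sign(diff), 0.0)
        else:
            t = diff / se
            p = 2.0 * float(sps.t.sf(abs(t), df_error))
        rows.append({"level_a": a, "level_b": b, "diff": float(diff),
                     "t": float(t), "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_raw"].to_numpy())
    out["significant"] = out["p_holm"] < alpha
    out["marginal"] = (out["p_holm"] >= alpha) & (out["p_holm"] < MARGINAL_ALPHA)
    return out


def pairwise_within_group(result: MixedAnovaResult, group: str,
                          alpha: float = ALPHA) -> pd.DataFrame:
    """Holm pairwise comparisons of within levels inside one group."""
    means = result.cell_means.loc[group]
    return holm_pairwise(means, result.ms_error_within, result.n_per_group,
                         result.df_error_within, alpha)


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float


def one_sample_t(values, mu: float) -> TTestResult:
    """Two-sided one-sample t-test against ``mu`` (df = n-1)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise InsufficientDataError("one-sample t-test needs n >= 2")
    if np.var(x, ddof=1) == 0:
        raise ParameterError("zero variance: t statistic undefined")
    res = sps.ttest_1samp(x, mu)
    return TTestResult(t=float(res.statistic), df=len(x) - 1,
                       p=float(res.pvalue))


def pearson_change_correlation(neural_change, score_changes) -> pd.DataFrame:
    """Pearson r between a neural change and per-item score changes.

    ``neural_change`` is a Series indexed by participant (e.g. theta
    power post3 - pre); ``score_changes`` is a DataFrame indexed by
    participant with one column per questionnaire item.  Rows are
    aligned on the participant index.
    """
    neural = pd.Series(neural_change).astype(float)
    scores = pd.DataFrame(score_changes).astype(float)
    common = neural.index.intersection(scores.index)
    if len(common) < 3:
        raise InsufficientDataError("correlation needs at least 3 paired rows")
    x = neural.loc[common].to_numpy()
    if np.var(x) == 0:
        raise ParameterError("zero variance in neural change")
    rows = []
    for item in scores.columns:
        y = scores.loc[common, item].to_numpy()
        if np.var(y) == 0:
            raise ParameterError(f"zero variance in scores for {item}")
        r, p = sps.pearsonr(x, y)
        rows.append({"item": item, "r": float(r), "p": float(p),
                     "n": len(common)})
    return pd.DataFrame(rows)


@dataclass
class BandAnalysis:
    """Per-band statistical report for the in-ear band-power table."""

    band: str
    anova: MixedAnovaResult
    simple: pd.DataFrame
    pairwise: pd.DataFrame | None  # None when gated out (omnibus n.s.)
    gated_in: bool


def analyze_band_powers(table: pd.DataFrame, alpha: float = ALPHA) -> dict:
    """Mixed ANOVA + simple effects + gated Holm post-hocs per band.

    ``table`` is the tidy output of
    :func:`totonou.spectral.band_power_table`; L and R channels are
    averaged per participant and stage before analysis.  Pairwise
    comparisons of sets inside the sauna group are only computed when the
    omnibus test (interaction or set main effect) and the sauna group's
    simple main effect are significant, mirroring standard post-hoc
    gating; otherwise ``pairwise`` is ``None`` (all comparisons n.s.).
    """
    out = {}
    for band in BANDS:
        sub = table[table["band"] == band]
        if sub.empty:
            continue
        values = (sub.groupby(["participant", "group", "stage"],
                              as_index=False)["power"].mean())
        res = mixed_anova(values, value="power", within="stage")
        simple = simple_main_effects(res)
        omnibus = (res.p("interaction") < alpha) or (res.p("within") < alpha)
        sauna_sig = bool(simple.set_index("group").loc["sauna", "significant"]) \
            if "sauna" in list(simple["group"]) else False
        gated_in = omnibus and sauna_sig
        pairwise = pairwise_within_group(res, "sauna", alpha) if gated_in else None
        out[band] = BandAnalysis(band=band, anova=res, simple=simple,
                                 pairwise=pairwise, gated_in=gated_in)
    return out
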