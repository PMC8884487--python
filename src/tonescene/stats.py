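"""Group-level inference and classification.

The centrepiece is :class:`GroupConditionModel`, a mixed-effects model of a
per-participant, per-condition neural measure with fixed effects for group
(TD vs ASD), coherence condition and their interaction, and one
condition-independent participant random intercept.  For the balanced
design the REML solution has a closed form via the classic between-/
within-participant stratum decomposition, and the scaled-Wald F tests
coincide with repeated-measures ANOVA F statistics; an exact permutation
fallback covers unbalanced tables.

Also here: per-condition two-sample contrasts, the repeated-split linear
SVM diagnosis classifier, neural-to-behaviour linear prediction, and age
residualisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "GroupConditionModel",
    "GroupConditionResults",
    "per_condition_contrast",
    "classify_diagnosis",
    "ClassifierResult",
    "predict_behavior",
    "BehaviorPrediction",
    "residualize_age",
]


@dataclass
class GroupConditionResults:
    """Fitted group x condition mixed model.

    F statistics use the between-participant stratum for the group effect
    (df N - g) and the within-participant stratum for condition and
    interaction (df (c-1)(N-g)).
    """

    response: str
    f_group: float
    p_group: float
    df_group: tuple[int, int]
    f_condition: float
    p_condition: float
    df_condition: tuple[int, int]
    f_interaction: float
    p_interaction: float
    df_interaction: tuple[int, int]
    var_participant: float
    var_residual: float
    n_participants: int
    n_conditions: int
    group_sizes: dict[str, int]
    method: str = "reml-stratum"

    def summary(self) -> str:
        g = ", ".join(f"{k} n={v}" for k, v in self.group_sizes.items())
        lines = [
            f"Mixed-effects group x condition model  [{self.method}]",
            f"response: {self.response}   participants: {self.n_participants} ({g})"
            f"   conditions: {self.n_conditions}",
            "-" * 72,
            f"{'effect':<20}{'F':>10}{'df':>12}{'p':>12}",
            f"{'group':<20}{self.f_group:>10.3f}{str(self.df_group):>12}"
            f"{self.p_group:>12.4g}",
            f"{'condition':<20}{self.f_condition:>10.3f}{str(self.df_condition):>12}"
            f"{self.p_condition:>12.4g}",
            f"{'group x condition':<20}{self.f_interaction:>10.3f}"
            f"{str(self.df_interaction):>12}{self.p_interaction:>12.4g}",
            "-" * 72,
            f"random effects: participant var {self.var_participant:.4g}, "
            f"residual var {self.var_residual:.4g}",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "effect": ["group", "condition", "group_x_condition"],
                "F": [self.f_group, self.f_condition, self.f_interaction],
                "df_num": [self.df_group[0], self.df_condition[0], self.df_interaction[0]],
                "df_den": [self.df_group[1], self.df_condition[1], self.df_interaction[1]],
                "p": [self.p_group, self.p_condition, self.p_interaction],
            }
        )


class GroupConditionModel:
    """Mixed model of a neural measure: group + condition + interaction,
    participant random intercept.

    Parameters
    ----------
    table
        Long-format table with one row per participant x condition.
    response
        Column holding the measure (e.g. ``"combined_z"``).
    """

    def __init__(
        self,
        table: pd.DataFrame,
        response: str = "combined_z",
        group_col: str = "group",
        condition_col: str = "condition_N",
        id_col: str = "participant_id",
    ):
        need = {response, group_col, condition_col, id_col}
        missing = need - set(table.columns)
        if missing:
            raise ValueError(f"table lacks columns {sorted(missing)}")
        self.table = table
        self.response = response
        self.group_col = group_col
        self.condition_col = condition_col
        self.id_col = id_col

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, response: str = "combined_z", **kw):
        return cls(table, response, **kw)

    def _wide(self) -> tuple[np.ndarray, np.ndarray, list]:
        """(values (N x c), group labels (N,), condition order) or raise."""
        t = self.table
        pivot = t.pivot_table(
            index=self.id_col, columns=self.condition_col, values=self.response,
            aggfunc="mean",
        )
        counts = t.groupby([self.id_col, self.condition_col]).size().unstack()
        if pivot.isna().any().any() or (counts != 1).any().any():
            raise ValueError("unbalanced design")
        groups = t.groupby(self.id_col)[self.group_col].first().reindex(pivot.index)
        if groups.nunique() < 2:
            raise ValueError("need two groups")
        return pivot.values, groups.values, list(pivot.columns)

    def fit(self, n_permutations: int = 999, seed: int = 0) -> GroupConditionResults:
        """REML stratum fit; permutation fallback when unbalanced."""
        try:
            y, groups, conds = self._wide()
        except ValueError as err:
            if "unbalanced" not in str(err):
                raise
            warnings.warn(
                "unbalanced design: falling back to a permutation test",
                stacklevel=2,
            )
            return self._fit_permutation(n_permutations, seed)
        return self._fit_balanced(y, groups, conds)

    def _anova_components(self, y: np.ndarray, groups: np.ndarray):
        """Stratum sums of squares for the balanced mixed ANOVA."""
        n, c = y.shape
        labels, inv = np.unique(groups, return_inverse=True)
        g = labels.size
        sub_means = y.mean(axis=1)
        group_means = np.array([sub_means[inv == k].mean() for k in range(g)])
        n_g = np.array([(inv == k).sum() for k in range(g)])
        grand = sub_means.mean()

        ss_group = c * float(np.sum(n_g * (group_means - grand) ** 2))
        ss_subj = c * float(np.sum((sub_means - group_means[inv]) ** 2))

        w = y - sub_means[:, None]  # within-participant deviations
        cond_means = w.mean(axis=0)
        rss_cond = float(np.sum((w - cond_means) ** 2))
        cell = np.stack([w[inv == k].mean(axis=0) for k in range(g)])
        rss_full = float(np.sum((w - cell[inv]) ** 2))
        ss_cond = float(np.sum(w**2)) - rss_cond
        ss_int = rss_cond - rss_full
        return labels, n_g, g, c, n, ss_group, ss_subj, ss_cond, ss_int, rss_full

    def _fit_balanced(self, y, groups, conds) -> GroupConditionResults:
        (labels, n_g, g, c, n,
         ss_group, ss_subj, ss_cond, ss_int, rss_full) = self._anova_components(y, groups)

        df_g, df_s = g - 1, n - g
        df_c, df_i = c - 1, (g - 1) * (c - 1)
        df_e = (c - 1) * (n - g)
        ms_subj = ss_subj / df_s
        ms_err = rss_full / df_e
        with np.errstate(divide="ignore", invalid="ignore"):
            f_group = float(np.float64(ss_group / df_g) / ms_subj)
            f_cond = float(np.float64(ss_cond / df_c) / ms_err)
            f_int = float(np.float64(ss_int / df_i) / ms_err)
        return GroupConditionResults(
            response=self.response,
            f_group=f_group,
            p_group=float(sps.f.sf(f_group, df_g, df_s)),
            df_group=(df_g, df_s),
            f_condition=f_cond,
            p_condition=float(sps.f.sf(f_cond, df_c, df_e)),
            df_condition=(df_c, df_e),
            f_interaction=f_int,
            p_interaction=float(sps.f.sf(f_int, df_i, df_e)),
            df_interaction=(df_i, df_e),
            var_participant=max((ms_subj - ms_err) / c, 0.0),
            var_residual=ms_err,
            n_participants=n,
            n_conditions=c,
            group_sizes={str(l): int(k) for l, k in zip(labels, n_g)},
        )

    def _fit_permutation(self, n_permutations: int, seed: int) -> GroupConditionResults:
        """Permutation inference on participants with complete conditions."""
        t = self.table
        pivot = t.pivot_table(
            index=self.id_col, columns=self.condition_col, values=self.response,
            aggfunc="mean",
        ).dropna()
        groups = (
            t.groupby(self.id_col)[self.group_col].first().reindex(pivot.index).values
        )
        y = pivot.values
        res = self._fit_balanced(y, groups, list(pivot.columns))
        rng = np.random.default_rng(seed)
        hits = np.zeros(3)
        obs = np.array([res.f_group, res.f_condition, res.f_interaction])
        for _ in range(n_permutations):
            perm = rng.permutation(groups)
            r = self._fit_balanced(y, perm, list(pivot.columns))
            hits += np.array([r.f_group, r.f_condition, r.f_interaction]) >= obs
        p = (hits + 1) / (n_permutations + 1)
        res.p_group, res.p_condition, res.p_interaction = map(float, p)
        res.method = f"permutation({n_permutations})"
        return res


def per_condition_contrast(
    table: pd.DataFrame,
    condition_n: int,
    response: str = "combined_z",
    group_col: str = "group",
    condition_col: str = "condition_N",
) -> tuple[float, float, int]:
    """Two-sample (pooled-variance) t test between groups at one condition.

    Returns (t, p, df) with df = n1 + n2 - 2.
    """
    sub = table[table[condition_col] == condition_n]
    labels = sorted(sub[group_col].unique())
    if len(labels) != 2:
        raise ValueError("need exactly two groups")
    a = sub.loc[sub[group_col] == labels[0], response].values
    b = sub.loc[sub[group_col] == labels[1], response].values
    if a.size == 0 or b.size == 0:
        raise ValueError("a group is empty at this condition")
    if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
        return 0.0, 1.0, int(a.size + b.size - 2)  # degenerate identical groups
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p), int(a.size + b.size - 2)


@dataclass
class ClassifierResult:
    """Repeated-split linear-SVM diagnosis classification."""

    accuracies_pct: np.ndarray
    features: tuple[str, ...]
    test_fraction: float
    n_repeats: int
    seed: int
    scheme: str

    @property
    def mean_accuracy_pct(self) -> float:
        return float(np.mean(self.accuracies_pct))

    @property
    def se_accuracy_pct(self) -> float:
        return float(np.std(self.accuracies_pct, ddof=1) / np.sqrt(self.n_repeats))

    def summary(self) -> str:
        return (
            f"linear SVM over {self.n_repeats} {self.scheme} "
            f"{int((1 - self.test_fraction) * 100)}/{int(self.test_fraction * 100)} "
            f"splits (seed {self.seed}): accuracy "
            f"{self.mean_accuracy_pct:.1f}% +- {self.se_accuracy_pct:.1f}% "
            f"(features: {', '.join(self.features)})"
        )


def classify_diagnosis(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    test_fraction: float = 0.10,
    n_repeats: int = 50,
    seed: int = 0,
    scheme: str = "repartition",
    C: float = 1.0,
) -> ClassifierResult:
    """Linear SVM diagnosis classification over repeated 90/10 splits.

    ``scheme='repartition'`` (default) draws 50 independent random
    partitions with no participant duplicated within a split;
    ``scheme='bootstrap'`` resamples the training portion with
    replacement.  Features are standardised on the training fold only.
    Splits whose training fold contains a single class are redrawn.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if np.unique(y).size != 2:
        raise ValueError("need exactly two classes")
    n = y.size
    n_test = max(1, int(round(test_fraction * n)))
    rng = np.random.default_rng(seed)
    accs = []
    while len(accs) < n_repeats:
        perm = rng.permutation(n)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        if scheme == "bootstrap":
            train_idx = rng.choice(train_idx, size=train_idx.size, replace=True)
        if np.unique(y[train_idx]).size < 2:
            continue  # redraw degenerate split
        scaler = StandardScaler().fit(X[train_idx])
        clf = SVC(kernel="linear", C=C).fit(scaler.transform(X[train_idx]), y[train_idx])
        acc = float(np.mean(clf.predict(scaler.transform(X[test_idx])) == y[test_idx]))
        accs.append(100.0 * acc)
    return ClassifierResult(
        accuracies_pct=np.asarray(accs),
        features=tuple(features.columns) if hasattr(features, "columns") else ("x",),
        test_fraction=test_fraction,
        n_repeats=n_repeats,
        seed=seed,
        scheme=scheme,
    )


@dataclass
class BehaviorPrediction:
    """Neural-to-behaviour linear prediction (in-sample, as reported)."""

    outcome: str
    features: tuple[str, ...]
    coefficients: np.ndarray  # intercept first
    predicted: np.ndarray
    observed: np.ndarray
    r: float
    p: float

    def summary(self) -> str:
        coefs = ", ".join(
            f"{n}={c:.3g}" for n, c in zip(("intercept",) + self.features, self.coefficients)
        )
        return (
            f"predicting {self.outcome} from [{', '.join(self.features)}]: "
            f"Pearson r(predicted, observed) = {self.r:.3f} (p = {self.p:.3g}); {coefs}"
        )


def predict_behavior(
    table: pd.DataFrame,
    outcome: str,
    feature_cols: tuple[str, ...],
) -> BehaviorPrediction:
    """Least-squares prediction of a behavioural score from neural measures.

    Fitted values are in-sample; the reported Pearson r between predicted
    and observed equals the regression's multiple correlation coefficient
    and is optimistically biased at small n (documented, not corrected).
    """
    sub = table.dropna(subset=[outcome, *feature_cols])
    if len(sub) < len(feature_cols) + 2:
        raise ValueError("fewer rows than predictors + 1")
    X = np.column_stack([np.ones(len(sub))] + [sub[c].values for c in feature_cols])
    yv = sub[outcome].values.astype(float)
    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    pred = X @ beta
    r, p = sps.pearsonr(pred, yv)
    return BehaviorPrediction(
        outcome=outcome,
        features=tuple(feature_cols),
        coefficients=beta,
        predicted=pred,
        observed=yv,
        r=float(r),
        p=float(p),
    )


def residualize_age(scores, ages) -> np.ndarray:
    """Residuals of scores regressed on age (age-corrected scores)."""
    s = np.asarray(scores, dtype=float)
    a = np.asarray(ages, dtype=float)
    if s.size < 3:
        raise ValueError("need at least 3 participants")
    if np.ptp(a) == 0:
        warnings.warn("constant age vector: returning centred scores", stacklevel=2)
        return s - s.mean()
    X = np.column_stack([np.ones_like(a), a])
    beta, *_ = np.linalg.lstsq(X, s, rcond=None)
    return s - X @ beta
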