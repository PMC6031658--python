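"""Study orchestration and statistics: within-subject baselines, subject
exclusion, leave-one-subject-out (LOSO) evaluation of the six inter-subject
decoders, binomial chance level, and the nonparametric test suite.

All six methods share the preprocessing front end; they differ in how
training subjects are combined:

======================  ====================================================
csp_lda                 SSD+CSP on the pooled training epochs, one LDA
csp_bagging             shared SSD+CSP, one LDA per training subject,
                        mean-probability aggregation
regcsp                  covariances shrunk toward a generic pool weighted by
                        the test subject's label-free covariance
pooling                 l1-logistic regression on pooled flattened epochs
l1_mtl / l21_mtl        multi-task logistic regression, one task per
                        training subject, l1 / l2,1 penalty
======================  ====================================================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from . import decoders, mtl, regcsp as rc
from .preprocessing import decimate
from .spectral import (DEFAULT_BAND_CENTER, DEFAULT_HALF_WIDTH, FeatureMatrix,
                       SpectralBand, butter_band, csp_from_covariances,
                       epoch_covariances, select_band, ssd_covariances,
                       ssd_from_covariances)
from .synthetic import EpochSet

log = logging.getLogger(__name__)

METHODS = ("csp_lda", "csp_bagging", "regcsp", "pooling", "l1_mtl", "l21_mtl")

DEFAULT_N_SSD = 20
DEFAULT_N_CSP = 10
# leave-one-task-out grid for the sparse-logistic regularization weight
DEFAULT_RHO_GRID = (0.5, 2.0, 8.0, 32.0)


# ---------------------------------------------------------------------------
# containers

@dataclass
class AccuracyTable:
    """Subjects x methods accuracy matrix (percent correct)."""

    values: np.ndarray
    subject_ids: list
    method_names: list
    modality: str
    training_condition: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != (len(self.subject_ids), len(self.method_names)):
            raise ValueError("values shape must be subjects x methods")
        if np.isnan(self.values).any():
            raise ValueError("missing cells are not allowed")
        if ((self.values < 0) | (self.values > 100)).any():
            raise ValueError("accuracies must lie in [0, 100]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids,
                            columns=self.method_names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, modality: str = "",
                   training_condition: str = "") -> "AccuracyTable":
        return cls(values=df.values, subject_ids=list(df.index),
                   method_names=list(df.columns), modality=modality,
                   training_condition=training_condition)


@dataclass
class ExclusionReport:
    mean_accuracies: dict  # subject_id -> mean within-subject accuracy
    excluded_ids: list
    k: int

    @property
    def retained_ids(self) -> list:
        return [s for s in self.mean_accuracies if s not in set(self.excluded_ids)]


# ---------------------------------------------------------------------------
# chance level and statistics

def chance_level(n_trials: int, alpha: float = 0.05) -> float:
    """Binomial significance threshold on decoding accuracy, in percent.

    Uses the binomial inverse-CDF convention: the threshold is k/n with
    k = ppf(1 - alpha) of Binomial(n, 1/2), i.e. accuracy strictly above the
    threshold occurs with probability < alpha under coin-flip decoding.
    For n = 80, alpha = 0.05 this gives 58.75%."""
    if n_trials < 1 or not 0 < alpha < 1:
        raise ValueError("need n_trials >= 1 and 0 < alpha < 1")
    k = int(stats.binom.ppf(1.0 - alpha, n_trials, 0.5))
    return 100.0 * k / n_trials


def exceeds_chance(accuracy_pct: float, n_trials: int,
                   alpha: float = 0.05) -> bool:
    """Strict exceedance of the binomial threshold."""
    return accuracy_pct > chance_level(n_trials, alpha)


def exclude_poor(mean_accuracies: dict, k: int = 5) -> ExclusionReport:
    """Discard the k subjects with the lowest mean within-subject accuracy
    from the training roster (ties broken by subject id)."""
    if k >= len(mean_accuracies):
        raise ValueError("k must be smaller than the subject count")
    ranked = sorted(mean_accuracies, key=lambda s: (mean_accuracies[s], s))
    return ExclusionReport(mean_accuracies=dict(mean_accuracies),
                           excluded_ids=sorted(ranked[:k]), k=k)


def friedman_test(table) -> tuple[float, float]:
    """Friedman rank test across method columns (rows = subjects).

    Midranks handle ties; the statistic carries the standard tie
    correction and is referred to chi-square with (methods - 1) df.  At
    least 3 method columns are required (the chi-square approximation is
    not defined for fewer)."""
    df = table.to_frame() if isinstance(table, AccuracyTable) else pd.DataFrame(table)
    if df.shape[0] < 2 or df.shape[1] < 3:
        raise ValueError("need at least 2 subjects and 3 methods")
    ranks = df.rank(axis=1)
    if np.allclose(ranks.var(axis=0, ddof=0).sum(), 0) and \
            np.allclose(df.var(axis=1, ddof=0).sum(), 0):
        return 0.0, 1.0  # identical columns: no information
    chi2, p = stats.friedmanchisquare(*[df[c].values for c in df.columns])
    return float(chi2), float(p)


def posthoc_multcompare(table, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise comparison of Friedman rank means with Bonferroni-adjusted
    normal-approximation p-values.

    Returns a tidy frame with one row per method pair: rank-mean difference,
    raw and adjusted p, and a significance flag at `alpha`."""
    df = table.to_frame() if isinstance(table, AccuracyTable) else pd.DataFrame(table)
    n, k = df.shape
    rank_means = df.rank(axis=1).mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    rows = []
    pairs = list(combinations(df.columns, 2))
    for a, b in pairs:
        diff = rank_means[a] - rank_means[b]
        z = diff / se
        p_raw = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(1.0, p_raw * len(pairs))
        rows.append({"method_a": a, "method_b": b,
                     "rank_mean_diff": diff, "p_raw": p_raw,
                     "p_adjusted": p_adj, "significant": p_adj < alpha})
    return pd.DataFrame(rows)


def compare_to_chance(column, n_trials: int, alpha: float = 0.05,
                      alternative: str = "greater") -> float:
    """One-sample t-test of per-subject accuracies against the binomial
    chance level (one-sided 'greater' by default)."""
    col = np.asarray(column, float)
    if len(col) < 2:
        raise ValueError("need at least 2 subjects")
    target = chance_level(n_trials, alpha)
    if np.allclose(col.std(ddof=1), 0.0):
        log.info("zero-variance accuracy column in compare_to_chance")
        if np.isclose(col.mean(), target):
            return 0.5  # boundary: all values exactly at chance
        return 0.0 if col.mean() > target else 1.0
    res = stats.ttest_1samp(col, popmean=target, alternative=alternative)
    return float(res.pvalue)


def paired_ttests(table) -> pd.DataFrame:
    """All-pairs two-sided paired t-tests, Bonferroni-corrected (multiplied
    by the number of pairs, capped at 1).  Diagonal = 1."""
    df = table.to_frame() if isinstance(table, AccuracyTable) else pd.DataFrame(table)
    cols = list(df.columns)
    n_pairs = len(cols) * (len(cols) - 1) // 2
    out = pd.DataFrame(np.ones((len(cols), len(cols))), index=cols, columns=cols)
    for a, b in combinations(cols, 2):
        d = df[a].values - df[b].values
        if np.allclose(d.std(ddof=1), 0.0):
            log.info("zero-variance difference for (%s, %s); p = 1", a, b)
            p = 1.0
        else:
            p = min(1.0, float(stats.ttest_rel(df[a], df[b]).pvalue) * n_pairs)
        out.loc[a, b] = out.loc[b, a] = p
    return out


# ---------------------------------------------------------------------------
# feature plumbing shared by the decoders

def default_band() -> SpectralBand:
    """Offline band of interest: 10 +/- 3 Hz for all subjects."""
    return SpectralBand(DEFAULT_BAND_CENTER, DEFAULT_HALF_WIDTH)


@dataclass
class _SubjectCspCache:
    """Per-subject sufficient statistics for the SSD+CSP front end: raw
    signal-band epoch covariances plus the SSD signal/flank covariance
    means.  SSD and CSP fits, and the log-power features, are all bilinear
    forms of these, so band-filtering happens once per subject."""

    sig_covs: np.ndarray  # epochs x ch x ch, unnormalized, signal band
    ssd_S: np.ndarray
    ssd_N: np.ndarray
    labels: np.ndarray
    subject_id: int


def _csp_cache(eset: EpochSet, band: SpectralBand) -> _SubjectCspCache:
    xb = butter_band(eset.data, band.lo, band.hi, eset.sfreq)
    S, N = ssd_covariances(eset.data, band, eset.sfreq)
    return _SubjectCspCache(
        sig_covs=epoch_covariances(xb, trace_norm=False), ssd_S=S, ssd_N=N,
        labels=np.asarray(eset.labels), subject_id=eset.subject_id)


def _fit_ssd_csp_cached(caches: list, n_ssd: int, n_csp: int):
    """Fit SSD on the pooled training epochs, then CSP in SSD space."""
    n_per = np.array([len(c.labels) for c in caches], float)
    w = n_per / n_per.sum()
    S = sum(wi * c.ssd_S for wi, c in zip(w, caches))
    N = sum(wi * c.ssd_N for wi, c in zip(w, caches))
    n_ch = S.shape[0]
    n_ssd = min(n_ssd, n_ch)
    ssd = ssd_from_covariances(S, N, n_ssd)
    # per-epoch covariance in SSD space, trace-normalized, averaged by class
    Wd = ssd.filters
    covs_z = np.concatenate([
        np.einsum("dk,edf,fm->ekm", Wd, c.sig_covs, Wd) for c in caches])
    tr = np.trace(covs_z, axis1=1, axis2=2)
    covs_z = covs_z / np.maximum(tr, 1e-300)[:, None, None]
    labels = np.concatenate([c.labels for c in caches])
    C1 = covs_z[labels > 0].mean(axis=0)
    C2 = covs_z[labels <= 0].mean(axis=0)
    n_csp = min(n_csp, n_ssd - n_ssd % 2)
    csp = csp_from_covariances(C1, C2, n_csp)
    return ssd, csp


def _features_cached(cache: _SubjectCspCache, ssd, csp) -> FeatureMatrix:
    W = ssd.filters @ csp.filters
    power = np.einsum("dk,edf,fk->ek", W, cache.sig_covs, W)
    feats = np.log(np.maximum(power, 1e-300))
    return FeatureMatrix(values=feats, labels=cache.labels,
                         subject_id=cache.subject_id,
                         feature_kind="csp_logpower")


def _fit_ssd_csp(train_sets: list[EpochSet], band: SpectralBand,
                 n_ssd: int, n_csp: int):
    caches = [_csp_cache(s, band) for s in train_sets]
    return _fit_ssd_csp_cached(caches, n_ssd, n_csp)


def _ssd_csp_features(eset: EpochSet, band: SpectralBand, ssd, csp) -> FeatureMatrix:
    return _features_cached(_csp_cache(eset, band), ssd, csp)


def flattened_features(eset: EpochSet, decimation_factor: int = 10) -> FeatureMatrix:
    """Decimated epoch time courses flattened to channel x time features."""
    dec = decimate(eset, decimation_factor)
    vals = dec.data.reshape(dec.n_epochs, -1)
    return FeatureMatrix(values=vals, labels=np.asarray(eset.labels),
                         subject_id=eset.subject_id,
                         feature_kind="flattened_timecourse")


# ---------------------------------------------------------------------------
# within-subject baselines

def within_subject_l1(features: FeatureMatrix, rho: float = 2.0,
                      folds: int = 10, **fit_opts) -> float:
    """Stratified k-fold cross-validated accuracy (percent) of l1-logistic
    regression on one subject's features."""
    if folds < 2:
        raise ValueError("need at least 2 folds")
    X, y = features.values, np.asarray(features.labels)
    counts = np.unique(y, return_counts=True)[1]
    if counts.min() < folds:
        raise ValueError("cannot stratify: a class has fewer samples than folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=False)
    accs = []
    for tr, te in skf.split(X, y):
        std = mtl.Standardizer(X[tr])
        model = mtl.fit_pooled_l1(std(X[tr]), y[tr], rho=rho, **fit_opts)
        pred = mtl.predict_unseen(model, std(X[te]))
        accs.append(np.mean(pred == y[te]))
    return 100.0 * float(np.mean(accs))


def within_subject_pm_csp(pm: EpochSet, mi: EpochSet,
                          rest: EpochSet | None = None,
                          n_ssd: int = DEFAULT_N_SSD,
                          n_csp: int = DEFAULT_N_CSP) -> float:
    """Train SSD+CSP+LDA on the subject's own passive movements, test on all
    of that subject's MI epochs (percent correct).  The band of interest is
    selected from rest vs PM when a rest set is given."""
    band = select_band(rest, pm) if rest is not None else default_band()
    ssd, csp = _fit_ssd_csp([pm], band, n_ssd, n_csp)
    train_feats = _ssd_csp_features(pm, band, ssd, csp)
    lda = decoders.fit_lda(train_feats)
    test_feats = _ssd_csp_features(mi, band, ssd, csp)
    pred, _ = decoders.predict_lda(lda, test_feats)
    return 100.0 * float(np.mean(pred == mi.labels))


# ---------------------------------------------------------------------------
# leave-one-subject-out evaluation

def _loso_predictor(method: str, pool: dict, training_condition: str,
                    roster: list, *, band: SpectralBand, n_ssd: int,
                    n_csp: int, decimation_factor: int, rho, rho_grid,
                    mtl_opts):
    """Build a fold predictor `predict(train_ids, test_id) -> labels`, with
    per-subject sufficient statistics computed once across folds."""
    if method in ("csp_lda", "csp_bagging"):
        train_caches = {s: _csp_cache(pool[s][training_condition], band)
                        for s in roster}
        test_caches: dict = {}

        def predict(train_ids, test_id):
            caches = [train_caches[s] for s in train_ids]
            ssd, csp = _fit_ssd_csp_cached(caches, n_ssd, n_csp)
            if test_id not in test_caches:
                test_caches[test_id] = _csp_cache(pool[test_id]["MI"], band)
            test_feats = _features_cached(test_caches[test_id], ssd, csp)
            if method == "csp_lda":
                feats = [_features_cached(c, ssd, csp) for c in caches]
                lda = decoders.fit_lda(
                    np.vstack([f.values for f in feats]),
                    np.concatenate([f.labels for f in feats]))
                return decoders.predict_lda(lda, test_feats)[0]
            members = [(c.subject_id,
                        decoders.fit_lda(_features_cached(c, ssd, csp)))
                       for c in caches]
            return decoders.bagged_predict(
                decoders.BaggedEnsemble(members), test_feats)

        return predict

    if method == "regcsp":
        prepared = {s: rc.prepare_regcsp_subject(pool[s][training_condition],
                                                 band) for s in roster}

        def predict(train_ids, test_id):
            return rc.regcsp_train_predict([prepared[s] for s in train_ids],
                                           pool[test_id]["MI"], band,
                                           n_components=n_csp)

        return predict

    # sparse-logistic family on flattened decimated time courses
    train_feats = {s: flattened_features(pool[s][training_condition],
                                         decimation_factor) for s in roster}
    test_feats: dict = {}

    def predict(train_ids, test_id):
        feats = [train_feats[s] for s in train_ids]
        std = mtl.Standardizer(np.vstack([f.values for f in feats]))
        tasks = mtl.TaskSet([mtl.Task(X=std(f.values), y=f.labels,
                                      subject_id=f.subject_id)
                             for f in feats])
        fold_rho = rho
        if fold_rho is None:
            fold_rho = mtl.select_rho(tasks, rho_grid, penalty="l21",
                                      **mtl_opts)
            log.info("selected rho=%g for %s (test subject %s)",
                     fold_rho, method, test_id)
        if method == "pooling":
            X = np.vstack([t.X for t in tasks.tasks])
            y = np.concatenate([t.y for t in tasks.tasks])
            model = mtl.fit_pooled_l1(X, y, rho=fold_rho, **mtl_opts)
        elif method == "l1_mtl":
            model = mtl.fit_mtl(tasks, rho=fold_rho, penalty="l1", **mtl_opts)
        else:  # l21_mtl; unknown methods rejected in run_loso
            model = mtl.fit_mtl(tasks, rho=fold_rho, penalty="l21", **mtl_opts)
        if test_id not in test_feats:
            test_feats[test_id] = flattened_features(pool[test_id]["MI"],
                                                     decimation_factor)
        return mtl.predict_unseen(model, std(test_feats[test_id].values))

    return predict


def run_loso(method: str, pool: dict, training_condition: str = "MI",
             roster: list | None = None, *,
             band: SpectralBand | None = None,
             n_ssd: int = DEFAULT_N_SSD, n_csp: int = DEFAULT_N_CSP,
             decimation_factor: int = 10, rho=None,
             rho_grid=DEFAULT_RHO_GRID, mtl_opts: dict | None = None) -> dict:
    """Leave-one-subject-out accuracies (percent) of one method.

    Every subject in `pool` is tested in turn on its MI epochs; the training
    set is the roster minus the test subject, using MI or PM epochs per
    `training_condition`.  Subjects outside the roster (excluded poor
    performers) are tested against the full roster.  No test-subject labels
    enter training; regcsp sees only the test subject's label-free
    covariance."""
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    if training_condition not in ("MI", "PM"):
        raise ValueError("training_condition must be 'MI' or 'PM'")
    if roster is None:
        roster = list(pool)
    if not roster:
        raise ValueError("empty training roster")
    band = band or default_band()
    mtl_opts = mtl_opts or {}
    predictor = _loso_predictor(method, pool, training_condition, roster,
                                band=band, n_ssd=n_ssd, n_csp=n_csp,
                                decimation_factor=decimation_factor, rho=rho,
                                rho_grid=rho_grid, mtl_opts=mtl_opts)
    accs = {}
    for test_id in pool:
        train_ids = [s for s in roster if s != test_id]
        if not train_ids:
            raise ValueError("empty training set for subject "
                             f"{test_id}; enlarge the roster")
        pred = predictor(train_ids, test_id)
        accs[test_id] = 100.0 * float(np.mean(pred == pool[test_id]["MI"].labels))
        log.info("LOSO %s (%s training): subject %s -> %.2f%%", method,
                 training_condition, test_id, accs[test_id])
    return accs


def run_all_methods(pool: dict, training_condition: str = "MI",
                    roster: list | None = None, methods=METHODS,
                    modality: str = "", **kw) -> AccuracyTable:
    """LOSO evaluation of several methods into one AccuracyTable."""
    cols = {m: run_loso(m, pool, training_condition, roster, **kw)
            for m in methods}
    subject_ids = list(pool)
    values = np.column_stack([[cols[m][s] for s in subject_ids]
                              for m in methods])
    return AccuracyTable(values=values, subject_ids=subject_ids,
                         method_names=list(methods), modality=modality,
                         training_condition=training_condition)
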