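"""Lead selection and ML-assisted ranking from NGS-derived statistics.

Covers per-cluster representative selection, liability-reduced alternatives,
cluster/epitope-bin concordance, the 0.005% binder-abundance heuristic,
cross-arm cluster overlap, Sanger-vs-NGS rank comparison, feature assembly
and the gradient-boosted binder classifier / affinity regressor with
bootstrap evaluation on a fixed train/test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr
from sklearn.metrics import (
    average_precision_score,
    confusion_matrix,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import train_test_split

from .annotation import ROI_NAMES, AnnotatedClone, roi_string

BINDER_KD_MOLAR = 1e-6  # affinity better than 1 uM against any target


@dataclass
class Characterization:
    """Experimental characterisation of one clone."""

    clone_id: str
    affinities: dict[str, float] = field(default_factory=dict)  # target -> KD (M)
    epitope_bin: str | None = None

    def __post_init__(self) -> None:
        if any(kd <= 0 for kd in self.affinities.values()):
            raise ValueError(f"clone {self.clone_id!r}: non-positive affinity")

    @property
    def binder(self) -> bool:
        return any(kd < BINDER_KD_MOLAR for kd in self.affinities.values())

    def best_kd(self, targets: Sequence[str] | None = None) -> float | None:
        """Best (lowest) monomeric KD among ``targets`` (all targets if None)."""
        kds = [kd for t, kd in self.affinities.items()
               if targets is None or t in targets]
        return min(kds) if kds else None


def load_characterization(path: str | Path) -> list[Characterization]:
    """TSV with columns clone_id, target, kd_molar, epitope_bin."""
    df = pd.read_csv(path, sep="\t", dtype={"clone_id": str, "target": str})
    missing = {"clone_id", "target", "kd_molar", "epitope_bin"} - set(df.columns)
    if missing:
        raise ValueError(f"characterization table missing columns: {sorted(missing)}")
    out: dict[str, Characterization] = {}
    for row in df.itertuples(index=False):
        c = out.setdefault(row.clone_id, Characterization(row.clone_id))
        if not pd.isna(row.kd_molar):
            c.affinities[row.target] = float(row.kd_molar)
        if isinstance(row.epitope_bin, str) and row.epitope_bin:
            c.epitope_bin = row.epitope_bin
    return list(out.values())


# ---------------------------------------------------------------------------
# Cluster-level selection
# ---------------------------------------------------------------------------

def select_representative(members: pd.DataFrame, by: str = "abundance") -> str:
    """clone_id of the cluster member maximising ``by`` (abundance or
    enrichment); ties break to the lexicographically smallest full-length
    sequence.  ``members`` needs columns clone_id, full_seq and the statistic."""
    if by not in ("abundance", "enrichment"):
        raise ValueError("by must be 'abundance' or 'enrichment'")
    if members.empty:
        raise ValueError("empty cluster")
    df = members.sort_values([by, "full_seq"], ascending=[False, True],
                             kind="mergesort")
    return str(df.iloc[0]["clone_id"])


def liability_alternatives(
    members: pd.DataFrame,
    fold_thresholds: Sequence[float] = (2.0, 5.0),
) -> pd.DataFrame:
    """Cluster members with strictly fewer liabilities than the abundance
    representative.

    ``members`` needs columns clone_id, full_seq, abundance, liabilities and
    optionally kd (molar).  When affinities are present each alternative is
    classed improved/similar/worse per fold threshold: improved when its KD is
    at least ``t``-fold lower than the representative's, worse when at least
    ``t``-fold higher.
    """
    rep_id = select_representative(members, by="abundance")
    rep = members.loc[members["clone_id"] == rep_id].iloc[0]
    rows = []
    has_kd = "kd" in members.columns and not pd.isna(rep.get("kd", np.nan))
    for row in members.itertuples(index=False):
        if row.clone_id == rep_id or row.liabilities >= rep["liabilities"]:
            continue
        entry = {
            "clone_id": row.clone_id,
            "delta_liabilities": int(row.liabilities - rep["liabilities"]),
        }
        for t in fold_thresholds:
            label = None
            if has_kd and not pd.isna(getattr(row, "kd", np.nan)):
                ratio = rep["kd"] / row.kd  # >1 means the member binds tighter
                label = "improved" if ratio >= t else "worse" if ratio <= 1 / t else "similar"
            entry[f"affinity_class_{t:g}x"] = label
        rows.append(entry)
    cols = ["clone_id", "delta_liabilities"] + [f"affinity_class_{t:g}x" for t in fold_thresholds]
    return pd.DataFrame(rows, columns=cols)


@dataclass(frozen=True)
class ConcordanceResult:
    consistent: int
    eligible: int

    @property
    def percent(self) -> float | None:
        return 100.0 * self.consistent / self.eligible if self.eligible else None


def bin_concordance(
    cluster_ids: Sequence[int],
    bins: Sequence[str | None],
    min_members: int = 2,
) -> ConcordanceResult:
    """Fraction of clusters whose characterised members all share one epitope bin.

    Inputs are aligned per characterised clone; entries with a missing bin are
    ignored.  Only clusters with >= ``min_members`` binned members are eligible.
    """
    groups: dict[int, list[str]] = {}
    for cid, b in zip(cluster_ids, bins):
        if b is None or (isinstance(b, float) and np.isnan(b)):
            continue
        groups.setdefault(int(cid), []).append(b)
    eligible = {cid: bs for cid, bs in groups.items() if len(bs) >= min_members}
    consistent = sum(1 for bs in eligible.values() if len(set(bs)) == 1)
    return ConcordanceResult(consistent=consistent, eligible=len(eligible))


def binder_heuristic(
    late_freqs: Mapping[str, float],
    threshold: float = 0.005,
) -> dict[str, bool]:
    """Binder call per clone from late-round concatenated-CDRs abundance:
    True iff relative frequency >= threshold percent (boundary inclusive)."""
    return {k: f >= threshold for k, f in late_freqs.items()}


def population_overlap(
    cluster_of: Mapping[str, int],
    arms_of: Mapping[str, Iterable[str]],
) -> dict[int, frozenset[str]]:
    """Per-cluster membership pattern across target arms (Venn classes).

    ``cluster_of`` maps ROI values to pooled cluster ids and ``arms_of`` maps
    each ROI value to the arms where it was observed.
    """
    pattern: dict[int, set[str]] = {}
    for v, cid in cluster_of.items():
        pattern.setdefault(cid, set()).update(arms_of.get(v, ()))
    return {cid: frozenset(arms) for cid, arms in pattern.items()}


def venn_counts(pattern: Mapping[int, frozenset[str]]) -> dict[frozenset[str], int]:
    out: dict[frozenset[str], int] = {}
    for arms in pattern.values():
        out[arms] = out.get(arms, 0) + 1
    return out


def compare_picked_clones(
    picked: Sequence[str],
    freqs: Mapping[str, float],
) -> pd.DataFrame:
    """Rank picked (e.g. Sanger) HCDR3s within the NGS frequency table.

    Rank 1 is the most frequent NGS value; ties break lexicographically.
    Values absent from the NGS table are flagged with found=False.
    """
    order = sorted(freqs, key=lambda v: (-freqs[v], v))
    rank = {v: i + 1 for i, v in enumerate(order)}
    rows = [
        {
            "picked": p,
            "found": p in freqs,
            "rank": rank.get(p),
            "frequency": freqs.get(p),
        }
        for p in picked
    ]
    return pd.DataFrame(rows, columns=["picked", "found", "rank", "frequency"])


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

FRAMEWORK_ORDER = ("LFR1", "LFR2", "LFR3", "LFR4", "HFR1", "HFR2", "HFR3", "HFR4")
PAD = "-"


def build_features(
    clones: Sequence[AnnotatedClone],
    stats_by_roi: Mapping[str, pd.DataFrame],
    cluster_of: Mapping[str, int] | None = None,
    cluster_roi: str = "HCDR3",
    chars: Sequence[Characterization] | None = None,
    regression_targets: Sequence[str] | None = None,
    one_hot_frameworks: bool = True,
) -> tuple[pd.DataFrame, pd.Series | None, pd.Series | None]:
    """Assemble the model matrix for a clone collection.

    Per ROI (HCDR3, HCDR3+LCDR3, CDRs, FULL when present in ``stats_by_roi``):
    log10 early/late relative frequency and log10 fold enrichment, floored at
    the smallest positive observed value of each column; clones lacking a ROI
    statistic are imputed with the floor and flagged.  Adds AbScan cluster
    size (# unique full-length clones per cluster), the liability count, and
    one-hot encoded framework residues over a fixed per-position vocabulary
    (21 symbols including the pad).

    Returns (X, y_binder, y_log10_kd); label series are None without ``chars``
    and regression labels are NaN where no monomeric affinity was measured.
    """
    index = [c.clone_id for c in clones]
    X = pd.DataFrame(index=index)
    flags = pd.Series(False, index=index)

    for roi_name, stats in stats_by_roi.items():
        if roi_name not in ROI_NAMES:
            raise ValueError(f"unknown ROI {roi_name!r}")
        table = stats.set_index("roi_value")
        for col in ("rel_freq_early", "rel_freq_late", "enrichment"):
            raw = []
            for clone in clones:
                v = roi_string(clone, roi_name)
                raw.append(table[col].get(v, np.nan))
            raw = np.asarray(raw, dtype=float)
            positive = raw[np.isfinite(raw) & (raw > 0)]
            floor = positive.min() if positive.size else 1.0
            flags |= pd.Series(~np.isfinite(raw), index=index)
            filled = np.where(np.isfinite(raw), np.maximum(raw, floor), floor)
            X[f"log10_{col}_{roi_name}"] = np.log10(filled)

    if cluster_of is not None:
        sizes: dict[int, int] = {}
        clone_cluster = {}
        for clone in clones:
            cid = cluster_of.get(roi_string(clone, cluster_roi))
            clone_cluster[clone.clone_id] = cid
            if cid is not None:
                sizes[cid] = sizes.get(cid, 0) + 1
        X["cluster_size"] = [
            sizes.get(clone_cluster[c.clone_id], 0) for c in clones
        ]

    X["liabilities"] = [c.liabilities for c in clones]
    X["imputed"] = flags.astype(int).to_numpy()

    if one_hot_frameworks:
        concat = ["".join(c.frameworks.get(r, "") for r in FRAMEWORK_ORDER)
                  for c in clones]
        width = max((len(s) for s in concat), default=0)
        padded = [s.ljust(width, PAD) for s in concat]
        onehot: dict[str, np.ndarray] = {}
        for pos in range(width):
            col = np.array([s[pos] for s in padded])
            symbols = sorted(set(col))
            if len(symbols) == 1:
                continue  # invariant position carries no signal
            for sym in symbols:
                onehot[f"fw{pos}_{sym}"] = (col == sym).astype(int)
        if onehot:
            X = pd.concat([X, pd.DataFrame(onehot, index=index)], axis=1)

    y_binder = y_kd = None
    if chars is not None:
        by_id = {c.clone_id: c for c in chars}
        y_binder = pd.Series(
            [by_id[i].binder if i in by_id else np.nan for i in index],
            index=index, name="binder",
        )
        kds = [by_id[i].best_kd(regression_targets) if i in by_id else None
               for i in index]
        y_kd = pd.Series(
            [np.log10(kd) if kd else np.nan for kd in kds],
            index=index, name="log10_kd",
        )
    return X, y_binder, y_kd


# ---------------------------------------------------------------------------
# Gradient-boosted ranking models
# ---------------------------------------------------------------------------

DEFAULT_SEARCH_SPACE: dict[str, Sequence] = {
    "n_estimators": (50, 100, 200),
    "max_depth": (2, 3, 4, 6),
    "learning_rate": (0.03, 0.1, 0.3),
    "subsample": (0.7, 1.0),
    "colsample_bytree": (0.7, 1.0),
    "min_child_weight": (1, 3),
}


@dataclass
class ModelConfig:
    task: str = "classify"  # classify | regress
    split: tuple[int, int] = (100, 100)
    bootstrap_reps: int = 100
    seed: int = 0
    n_search: int = 25
    search_space: Mapping[str, Sequence] = field(
        default_factory=lambda: dict(DEFAULT_SEARCH_SPACE)
    )

    def __post_init__(self) -> None:
        if self.task not in ("classify", "regress"):
            raise ValueError("task must be 'classify' or 'regress'")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")


def _make_model(task: str, params: Mapping, seed: int):
    import xgboost as xgb

    common = dict(params, random_state=seed, n_jobs=1, tree_method="hist",
                  verbosity=0)
    if task == "classify":
        return xgb.XGBClassifier(eval_metric="logloss", **common)
    return xgb.XGBRegressor(**common)


def _score(task: str, model, X, y) -> float:
    if task == "classify":
        if len(np.unique(y)) < 2:
            return np.nan
        return average_precision_score(y, model.predict_proba(X)[:, 1])
    pred = model.predict(X)
    rho = spearmanr(y, pred).statistic
    return rho if np.isfinite(rho) else np.nan


def train_eval(X, y, cfg: ModelConfig) -> dict:
    """Fit and evaluate the gradient-boosted model on a fixed split.

    The train half is bootstrap-resampled: out-of-bag scores select the
    hyperparameters (seeded random search over ``cfg.search_space``) and,
    with the selected parameters, ``cfg.bootstrap_reps`` refits evaluated on
    the held-out test half give the reported metric distributions.

    Returns a report dict with the fitted model, test metrics (confusion
    matrix / precision / recall / ROC AUC / PR AUC for classification;
    Pearson and Spearman of predicted vs measured log10 KD for regression),
    bootstrap metric arrays and the top-5 features by importance.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y)
    train_size, test_size = cfg.split
    if train_size + test_size > len(y):
        raise ValueError(
            f"split {cfg.split} exceeds the {len(y)} available observations")
    classify = cfg.task == "classify"
    if classify:
        y = y.astype(int)
    stratify = y if classify and len(np.unique(y)) > 1 else None
    X_train, X_test, y_train, y_test = train_test_split(
        X, y, train_size=train_size, test_size=test_size,
        random_state=cfg.seed, stratify=stratify,
    )
    if classify and len(np.unique(y_train)) < 2:
        raise ValueError("training labels contain a single class")

    rng = np.random.default_rng(cfg.seed)
    n_train = len(y_train)
    Xtr = X_train.to_numpy()
    keys = sorted(cfg.search_space)

    def bootstrap_scores(params: Mapping, reps: int, eval_on_test: bool):
        scores = []
        for _ in range(reps):
            idx = rng.integers(0, n_train, n_train)
            oob = np.setdiff1d(np.arange(n_train), idx)
            yb = y_train[idx]
            if classify and len(np.unique(yb)) < 2:
                continue
            model = _make_model(cfg.task, params, cfg.seed)
            model.fit(Xtr[idx], yb)
            if eval_on_test:
                if classify:
                    prob = model.predict_proba(X_test.to_numpy())[:, 1]
                    scores.append({
                        "roc_auc": roc_auc_score(y_test, prob),
                        "pr_auc": average_precision_score(y_test, prob),
                    })
                else:
                    pred = model.predict(X_test.to_numpy())
                    scores.append({
                        "pearson": pearsonr(y_test, pred).statistic,
                        "spearman": spearmanr(y_test, pred).statistic,
                    })
            else:
                if oob.size == 0:
                    continue
                s = _score(cfg.task, model, Xtr[oob], y_train[oob])
                if np.isfinite(s):
                    scores.append(s)
        return scores

    # seeded random hyperparameter search scored by mean bootstrap OOB metric
    best_params, best_score = None, -np.inf
    for _ in range(max(1, cfg.n_search)):
        params = {k: cfg.search_space[k][rng.integers(len(cfg.search_space[k]))]
                  for k in keys}
        scores = bootstrap_scores(params, max(2, cfg.bootstrap_reps // 5), False)
        mean = float(np.mean(scores)) if scores else -np.inf
        if mean > best_score:
            best_params, best_score = params, mean

    model = _make_model(cfg.task, best_params, cfg.seed)
    model.fit(Xtr, y_train)

    report: dict = {
        "task": cfg.task,
        "params": best_params,
        "n_train": n_train,
        "n_test": len(y_test),
        "model": model,
    }
    if classify:
        prob = model.predict_proba(X_test.to_numpy())[:, 1]
        pred = (prob >= 0.5).astype(int)
        report["class_balance"] = {
            "train": float(np.mean(y_train)), "test": float(np.mean(y_test))}
        report["metrics"] = {
            "confusion_matrix": confusion_matrix(y_test, pred).tolist(),
            "precision": float(precision_score(y_test, pred, zero_division=0)),
            "recall": float(recall_score(y_test, pred, zero_division=0)),
            "roc_auc": float(roc_auc_score(y_test, prob)),
            "pr_auc": float(average_precision_score(y_test, prob)),
        }
    else:
        pred = model.predict(X_test.to_numpy())
        report["metrics"] = {
            "pearson": float(pearsonr(y_test, pred).statistic),
            "spearman": float(spearmanr(y_test, pred).statistic),
        }
    boots = bootstrap_scores(best_params, cfg.bootstrap_reps, True)
    report["bootstrap"] = {
        k: np.array([b[k] for b in boots]) for k in (boots[0] if boots else {})
    }
    importance = sorted(
        zip(X.columns, model.feature_importances_), key=lambda kv: -kv[1]
    )
    report["feature_importance"] = importance
    report["top5_features"] = [name for name, _ in importance[:5]]
    return report
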