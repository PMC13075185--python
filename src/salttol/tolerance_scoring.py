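"""Membership-function scoring and tolerance classification.

Per-trait STIs are min-max scaled across genotypes to membership function
values (MFV in [0, 1]); their unweighted mean per genotype is the average
membership function value (AMFV), the multi-trait tolerance score. Genotypes
are classified into five ordinal classes from the AMFV distribution's mean
and sample standard deviation:

    HT  AMFV >= mean + 1.64 SD
    T   mean + 1 SD <= AMFV < mean + 1.64 SD
    MT  mean - 1 SD <= AMFV < mean + 1 SD
    S   mean - 1.64 SD <= AMFV < mean - 1 SD
    HS  AMFV < mean - 1.64 SD

Cross-stage dynamics compare a genotype's class at two developmental stages
under the ordinal order HS < S < MT < T < HT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

CLASSES = ["HS", "S", "MT", "T", "HT"]  # ordinal, worst to best
_RANK = {c: i for i, c in enumerate(CLASSES)}


class MembershipScaler(BaseEstimator, TransformerMixin):
    """Column-wise min-max scaler mapping each trait's STI to [0, 1].

    Unlike a generic range scaler this refuses degenerate columns (a trait
    identical across genotypes has no defined membership) and clamps only
    floating-point drift. Fits per stage across genotypes.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D matrix with >= 2 genotypes")
        self.min_ = np.nanmin(X, axis=0)
        self.max_ = np.nanmax(X, axis=0)
        degenerate = np.where(self.max_ - self.min_ <= 0)[0]
        if len(degenerate):
            names = getattr(self, "feature_names_", None)
            label = ([names[i] for i in degenerate] if names is not None
                     else degenerate.tolist())
            raise ValueError(f"degenerate trait(s) with Xmax == Xmin: {label}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        scaled = (X - self.min_) / (self.max_ - self.min_)
        return np.clip(scaled, 0.0, 1.0)


def compute_mfv(sti: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale STIs per (stage, trait) across genotypes.

    Input columns: genotype_id, stage, trait, sti. Flagged (NaN) STIs are
    dropped with their records. Returns the same layout with an ``mfv``
    column.
    """
    sti = sti.dropna(subset=["sti"])
    out = []
    for (stage, trait), grp in sti.groupby(["stage", "trait"], sort=False):
        scaler = MembershipScaler()
        scaler.feature_names_ = [trait]
        vals = grp["sti"].to_numpy()[:, None]
        mfv = scaler.fit(vals).transform(vals)[:, 0]
        out.append(pd.DataFrame({
            "genotype_id": grp["genotype_id"].to_numpy(),
            "stage": stage, "trait": trait, "mfv": mfv}))
    return pd.concat(out, ignore_index=True)


def compute_amfv(mfv: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean MFV per genotype within each stage.

    Every genotype must have an MFV for every trait of its stage; gaps are
    reported by genotype/trait.
    """
    res = []
    for stage, grp in mfv.groupby("stage", sort=False):
        traits = grp["trait"].unique()
        wide = grp.pivot(index="genotype_id", columns="trait", values="mfv")
        holes = wide.isna()
        if holes.to_numpy().any():
            where = [(g, t) for g, row in holes.iterrows()
                     for t in traits if row.get(t, True)]
            raise ValueError(f"missing MFV at stage {stage!r}: {where[:10]}")
        res.append(pd.DataFrame({
            "genotype_id": wide.index, "stage": stage,
            "amfv": wide.mean(axis=1).to_numpy()}))
    return pd.concat(res, ignore_index=True)


@dataclass
class ClassificationThresholds:
    """Cut points derived from the AMFV sample mean and sample SD (n-1)."""

    mean: float
    sd: float

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("SD must be positive")

    @classmethod
    def from_scores(cls, amfv) -> "ClassificationThresholds":
        a = np.asarray(amfv, float)
        return cls(mean=float(a.mean()), sd=float(a.std(ddof=1)))

    @property
    def cuts(self) -> tuple[float, float, float, float]:
        m, s = self.mean, self.sd
        return (m - 1.64 * s, m - s, m + s, m + 1.64 * s)

    def to_dict(self) -> dict:
        lo164, lo1, hi1, hi164 = self.cuts
        return {"mean": self.mean, "sd": self.sd,
                "mean_minus_1.64sd": lo164, "mean_minus_1sd": lo1,
                "mean_plus_1sd": hi1, "mean_plus_1.64sd": hi164}


def classify(amfv, thresholds: ClassificationThresholds):
    """Assign the five tolerance classes; lower bounds inclusive.

    Accepts a scalar or array; returns a string or array of strings.
    """
    a = np.asarray(amfv, dtype=float)
    lo164, lo1, hi1, hi164 = thresholds.cuts
    idx = np.digitize(a, [lo164, lo1, hi1, hi164], right=False)
    if a.ndim == 0:
        return CLASSES[int(idx)]
    return np.array(CLASSES, dtype=object)[idx]


class ToleranceClassifier(BaseEstimator):
    """Sklearn-style wrapper: fit learns the AMFV mean/SD thresholds from
    the analysed sample, predict maps AMFVs to the five classes."""

    def fit(self, X, y=None):
        a = np.asarray(X, float).ravel()
        self.thresholds_ = ClassificationThresholds.from_scores(a)
        return self

    def predict(self, X):
        a = np.asarray(X, float).ravel()
        return classify(a, self.thresholds_)

    def fit_predict(self, X, y=None):
        return self.fit(X).predict(X)


def classify_stage(amfv: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Classify every genotype within each stage from that stage's own AMFV
    distribution. Returns (scores with a ``tolerance_class`` column,
    thresholds per stage)."""
    out, thr = [], {}
    for stage, grp in amfv.groupby("stage", sort=False):
        t = ClassificationThresholds.from_scores(grp["amfv"])
        thr[stage] = t
        g = grp.copy()
        g["tolerance_class"] = classify(grp["amfv"].to_numpy(), t)
        out.append(g)
    return pd.concat(out, ignore_index=True), thr


# ----------------------------------------------------------------------
# cross-stage dynamics

def cross_stage(scores_stage1: pd.DataFrame,
                scores_stage2: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Transitions between tolerance classes across two stages.

    Both inputs need columns genotype_id and tolerance_class over the same
    genotype set. Returns the long-format transition table (genotype,
    class_stage1, class_stage2, direction) and a summary of counts and
    percentages (1 decimal) per direction.
    """
    s1 = scores_stage1.set_index("genotype_id")["tolerance_class"]
    s2 = scores_stage2.set_index("genotype_id")["tolerance_class"]
    only1 = sorted(set(s1.index) - set(s2.index))
    only2 = sorted(set(s2.index) - set(s1.index))
    if only1 or only2:
        raise ValueError(f"genotypes present in only one stage: "
                         f"stage1-only {only1[:5]}, stage2-only {only2[:5]}")
    s2 = s2.reindex(s1.index)
    r1 = s1.map(_RANK).to_numpy()
    r2 = s2.map(_RANK).to_numpy()
    direction = np.where(r2 > r1, "improved",
                         np.where(r2 < r1, "declined", "stable"))
    table = pd.DataFrame({"genotype_id": s1.index,
                          "class_stage1": s1.to_numpy(),
                          "class_stage2": s2.to_numpy(),
                          "direction": direction})
    summary = transition_summary(table["direction"])
    return table, summary


def transition_summary(directions) -> dict:
    """Counts and percentages (to 1 decimal) per transition direction."""
    d = pd.Series(directions)
    n = len(d)
    counts = {k: int((d == k).sum()) for k in ("improved", "declined",
                                               "stable")}
    pct = {k: round(100.0 * v / n, 1) for k, v in counts.items()}
    return {"n": n, "counts": counts, "percentages": pct}
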