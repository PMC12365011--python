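"""Per-fork replication-stress signatures: features, embedding, clustering.

Each fork is summarised by eight features: the total fork-track length,
the EdU and BrdU track lengths, the four cross/within-analogue positive
call fractions inside each segment, and the stall score.  Features are
robust-rescaled (median/IQR) across forks, embedded into two dimensions
with UMAP (25 nearest neighbours, min_dist 0, Chebyshev metric), and
clustered with K-means (K = 5); a confusion table of cluster versus
treatment condition supports a purity readout.  Excluding the three
length features ("no-speed" mode) probes whether conditions separate on
analogue-incorporation quality alone.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from forktrace.metrics import StallResult
from forktrace.trackio import AnalogueTrack, ForkCall

logger = logging.getLogger(__name__)

FEATURE_NAMES = [
    "track_length", "edu_length", "brdu_length",
    "frac_brdu_in_edu", "frac_edu_in_edu",
    "frac_edu_in_brdu", "frac_brdu_in_brdu",
    "stall_score",
]
LENGTH_FEATURES = ["track_length", "edu_length", "brdu_length"]


@dataclass(frozen=True)
class EmbeddingParams:
    """UMAP + K-means settings for the stress-signature embedding."""

    n_neighbors: int = 25
    min_dist: float = 0.0
    metric: str = "chebyshev"
    k_clusters: int = 5
    forks_per_run: int = 125
    seed: int = 0
    cluster_in_embedding: bool = True  # K-means on the 2-d embedding (else on rescaled features)


def _segment_fractions(track: AnalogueTrack, start: int, end: int,
                       threshold: float = 0.5) -> tuple[float, float]:
    """(fraction EdU-positive, fraction BrdU-positive) of thymidines in [start, end)."""
    lo = np.searchsorted(track.positions, start, side="left")
    hi = np.searchsorted(track.positions, end, side="left")
    if hi == lo:
        return 0.0, 0.0
    n = hi - lo
    fe = float((track.p_edu[lo:hi] > threshold).sum()) / n
    fb = float((track.p_brdu[lo:hi] > threshold).sum()) / n
    return fe, fb


def fork_features(track: AnalogueTrack, fork: ForkCall, stall: StallResult,
                  threshold: float = 0.5) -> np.ndarray | None:
    """The 8-feature signature vector for one fork, or None if the stall
    score was declined (such forks are skipped, with a log message)."""
    if not stall.ok:
        logger.info("fork on %s skipped from signatures: stall declined (%s)",
                    fork.read_id, stall.declined)
        return None
    edu_fe, edu_fb = _segment_fractions(track, fork.edu_segment.start,
                                        fork.edu_segment.end, threshold)
    brdu_fe, brdu_fb = _segment_fractions(track, fork.brdu_segment.start,
                                          fork.brdu_segment.end, threshold)
    return np.array([
        float(fork.track_length),
        float(fork.edu_segment.length),
        float(fork.brdu_segment.length),
        edu_fb, edu_fe, brdu_fe, brdu_fb,
        stall.score,
    ])


def features_from_table(table: pd.DataFrame) -> pd.DataFrame:
    """Derive the 8 signature columns from a per-fork metric table.

    Forks with a declined stall score are dropped.  Provenance columns
    (``condition``, ``run_id``, ``replicate_id``) are carried through.
    """
    df = table[table["stall_declined"] == ""].copy() if "stall_declined" in table else table.copy()
    out = pd.DataFrame({
        "track_length": (df["track_end"] - df["track_start"]).astype(float),
        "edu_length": (df["edu_end"] - df["edu_start"]).astype(float),
        "brdu_length": (df["brdu_end"] - df["brdu_start"]).astype(float),
        "frac_brdu_in_edu": df["frac_brdu_in_edu"],
        "frac_edu_in_edu": df["frac_edu_in_edu"],
        "frac_edu_in_brdu": df["frac_edu_in_brdu"],
        "frac_brdu_in_brdu": df["frac_brdu_in_brdu"],
        "stall_score": df["stall_score"],
    }, index=df.index)
    for col in ("condition", "run_id", "replicate_id"):
        if col in df:
            out[col] = df[col]
    return out.reset_index(drop=True)


def robust_rescale(matrix: np.ndarray) -> np.ndarray:
    """Rescale each feature column to (x - median) / IQR.

    A column with zero IQR is set to zero (with a warning): it carries no
    information at this sample size.
    """
    X = np.asarray(matrix, dtype=np.float64)
    if X.shape[0] < 4:
        raise ValueError("robust rescaling needs at least 4 forks")
    med = np.median(X, axis=0)
    q75, q25 = np.percentile(X, [75, 25], axis=0)
    iqr = q75 - q25
    out = np.zeros_like(X)
    for j in range(X.shape[1]):
        if iqr[j] == 0:
            warnings.warn(f"feature column {j} has zero IQR; set to 0", stacklevel=2)
            continue
        out[:, j] = (X[:, j] - med[j]) / iqr[j]
    return out


def subsample_per_run(features: pd.DataFrame, forks_per_run: int, seed: int,
                      run_column: str = "run_id") -> pd.DataFrame:
    """Seeded subsample of at most ``forks_per_run`` forks per sequencing run.

    Runs with fewer forks contribute all of them (with a warning).  The
    returned frame preserves the sampled row identity so a manifest can
    regenerate the exact subset.
    """
    rng = np.random.default_rng(seed)
    parts = []
    for run, grp in features.groupby(run_column, sort=True):
        if len(grp) < forks_per_run:
            warnings.warn(f"run {run!r} has only {len(grp)} forks "
                          f"(< {forks_per_run}); using all", stacklevel=2)
            parts.append(grp)
        else:
            idx = rng.choice(len(grp), size=forks_per_run, replace=False)
            parts.append(grp.iloc[np.sort(idx)])
    return pd.concat(parts, axis=0)


def embed_and_cluster(features: pd.DataFrame,
                      params: EmbeddingParams = EmbeddingParams(),
                      exclude_speed: bool = False,
                      condition_column: str = "condition",
                      run_column: str = "run_id") -> dict:
    """Embed rescaled signatures with UMAP and cluster with K-means.

    ``features`` must hold the 8 feature columns (:data:`FEATURE_NAMES`)
    plus ``condition`` and ``run_id`` provenance columns.  With
    ``exclude_speed`` the three track-length features are dropped before
    rescaling, leaving the 5-dimensional incorporation/stall space.

    Returns a dict with ``embedding`` (n x 2), ``labels``, ``centroids``
    (in embedding space), ``confusion`` (cluster x condition table),
    ``purity``, and the subsampled ``frame``.
    """
    import umap  # deferred: heavy import

    from sklearn.cluster import KMeans

    sub = subsample_per_run(features, params.forks_per_run, params.seed, run_column)
    cols = [c for c in FEATURE_NAMES if not (exclude_speed and c in LENGTH_FEATURES)]
    X = robust_rescale(sub[cols].to_numpy(dtype=np.float64))

    n_neighbors = min(params.n_neighbors, max(2, len(sub) - 1))
    reducer = umap.UMAP(n_neighbors=n_neighbors, min_dist=params.min_dist,
                        metric=params.metric, random_state=params.seed)
    emb = reducer.fit_transform(X)

    km_space = emb if params.cluster_in_embedding else X
    km = KMeans(n_clusters=params.k_clusters, n_init=10, random_state=params.seed)
    labels = km.fit_predict(km_space)

    confusion = pd.crosstab(pd.Series(labels, name="cluster", index=sub.index),
                            sub[condition_column])
    purity = float(confusion.max(axis=1).sum() / confusion.values.sum())
    centroids = km.cluster_centers_ if params.cluster_in_embedding else np.vstack(
        [emb[labels == k].mean(axis=0) for k in range(params.k_clusters)])
    return {
        "embedding": emb,
        "labels": labels,
        "centroids": centroids,
        "confusion": confusion,
        "purity": purity,
        "frame": sub,
    }


def kde_density(embedding: np.ndarray):
    """Gaussian KDE over the 2-d embedding (default bandwidth), for the
    density panel of the signature plot."""
    from scipy.stats import gaussian_kde

    return gaussian_kde(embedding.T)


def plot_embedding(result: dict, out_path, condition_column: str = "condition"):
    """Two-panel signature figure: the embedding coloured by condition with
    K-means centroids, and a Gaussian-KDE density view (default bandwidth)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    emb = result["embedding"]
    frame = result["frame"]
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(11, 5))
    sns.scatterplot(x=emb[:, 0], y=emb[:, 1],
                    hue=frame[condition_column].to_numpy(), s=12, ax=ax1,
                    linewidth=0)
    ax1.scatter(result["centroids"][:, 0], result["centroids"][:, 1],
                marker="P", s=120, c="red", edgecolors="black", label="centroid")
    ax1.set_xlabel("UMAP 1")
    ax1.set_ylabel("UMAP 2")
    ax1.legend(fontsize=7, markerscale=1.5)
    sns.kdeplot(x=emb[:, 0], y=emb[:, 1], fill=True, cmap="coolwarm",
                thresh=0.02, ax=ax2)
    ax2.set_xlabel("UMAP 1")
    ax2.set_ylabel("UMAP 2")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
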