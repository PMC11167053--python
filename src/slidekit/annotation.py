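"""Staining-based cell-type annotation from per-cell channel means.

Raw mean intensities are variance-stabilised per channel with
``X'_j = arcsinh(X_j / (5 * Q(0.2, X_j)))`` where ``Q(0.2, X_j)`` is the
channel's 20th percentile (linear-interpolation quantile).  Each cell is
then labelled by the population mapped to the marker channel with the
highest preprocessed intensity.  The transform is strictly monotone per
channel and invariant to rescaling a channel by any positive factor, so
annotation does not depend on per-channel gain.
"""

from __future__ import annotations

import numpy as np

from .core import ChannelMatrix, ValidationError

QUANTILE = 0.2       # reference quantile of each channel
DIVISOR_FACTOR = 5.0  # arcsinh(X / (factor * quantile))
UNASSIGNED = "unassigned"


def preprocess_intensities(X: ChannelMatrix) -> ChannelMatrix:
    """Apply the arcsinh-of-scaled-quantile transform channel by channel.

    If a channel's 20th percentile is 0 the divisor falls back to 5x the
    smallest positive value of the column; an all-zero column is left at 0.
    """
    raw = np.asarray(X.X, float)
    if np.any(raw < 0):
        raise ValidationError("channel intensities must be non-negative")
    out = np.zeros_like(raw)
    for j in range(raw.shape[1]):
        col = raw[:, j]
        q = np.quantile(col, QUANTILE)  # linear interpolation (numpy default)
        if q <= 0:
            positive = col[col > 0]
            if positive.size == 0:
                continue
            q = positive.min()
        out[:, j] = np.arcsinh(col / (DIVISOR_FACTOR * q))
    return ChannelMatrix(out, list(X.channels), X.cell_ids)


def annotate_by_markers(X_prime: ChannelMatrix, marker_map: dict[str, str],
                        ) -> list[str]:
    """Label each cell by the population whose marker channel scores highest.

    Ties go to the lowest channel index; cells with zero signal on every
    marker channel are labelled "unassigned".
    """
    if not marker_map:
        raise ValidationError("marker_map must name at least one channel")
    missing = set(marker_map) - set(X_prime.channels)
    if missing:
        raise ValidationError(f"marker channels not in matrix: {sorted(missing)}")
    # marker columns in channel order so argmax ties resolve to the lowest index
    cols = [j for j, ch in enumerate(X_prime.channels) if ch in marker_map]
    sub = X_prime.X[:, cols]
    winners = np.argmax(sub, axis=1)
    labels = []
    for i, w in enumerate(winners):
        if np.all(sub[i] == 0):
            labels.append(UNASSIGNED)
        else:
            labels.append(marker_map[X_prime.channels[cols[w]]])
    return labels


def refine_by_clusters(labels: list[str], clusters) -> list[str]:
    """Relabel every cluster to its majority label (ties: lexicographically
    smallest).  Accepts any per-cell clustering, e.g. Leiden communities."""
    clusters = list(clusters)
    if len(clusters) != len(labels):
        raise ValidationError("clusters must be defined for every cell")
    majority: dict = {}
    for cl in set(clusters):
        members = [lab for lab, c in zip(labels, clusters) if c == cl]
        counts: dict[str, int] = {}
        for lab in members:
            counts[lab] = counts.get(lab, 0) + 1
        best = max(counts.values())
        majority[cl] = min(lab for lab, n in counts.items() if n == best)
    return [majority[c] for c in clusters]
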