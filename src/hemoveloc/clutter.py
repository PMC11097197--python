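"""SVD-based clutter filtering of ultrasound-style image sequences.

Strong, slowly varying tissue signal occupies the first few singular
components of the Casorati matrix (pixels x frames); tracer/bubble
signal and noise live in the higher components.  Filtering keeps the
components in a (low, high] rank band.  Rank thresholds are found
semi-automatically from the similarity matrix of the spatial singular
vectors: clutter components share the same spatial energy support and
therefore correlate strongly in magnitude, while flow and noise
components do not.  Note the correlation is computed between
*magnitudes* of the spatial vectors — the vectors themselves are
orthogonal by construction, so raw correlation carries no information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .types import ParticleImageSequence

__all__ = [
    "SvdDecomposition",
    "casorati_svd",
    "select_rank_thresholds",
    "svd_filter",
]


@dataclass
class SvdDecomposition:
    """Thin SVD of the Casorati matrix of an image sequence.

    ``spatial`` holds the image-shaped left singular vectors
    (rank, ny, nx); ``temporal`` the right singular vectors
    (rank, n_frames); singular values are sorted descending.
    """

    singular_values: np.ndarray
    spatial: np.ndarray
    temporal: np.ndarray
    frame_shape: Tuple[int, int]
    low: Optional[int] = None
    high: Optional[int] = None

    def __post_init__(self) -> None:
        s = self.singular_values
        if np.any(s < -1e-12):
            raise ValueError("singular values must be non-negative")
        if np.any(np.diff(s) > 1e-9 * max(s[0], 1.0)):
            raise ValueError("singular values must be sorted descending")

    @property
    def rank(self) -> int:
        return int(self.singular_values.size)

    def reconstruct(self, low: int = 0, high: Optional[int] = None) -> np.ndarray:
        """Frames rebuilt from components with 1-based index in (low, high]."""
        if high is None:
            high = self.rank
        if not (0 <= low < high <= self.rank):
            raise ValueError(f"need 0 <= low < high <= rank, got ({low}, {high})")
        sl = slice(low, high)
        ny, nx = self.frame_shape
        u = self.spatial[sl].reshape(high - low, ny * nx).T  # (px, k)
        sv = self.singular_values[sl]
        vt = self.temporal[sl]  # (k, nt)
        m = (u * sv) @ vt  # (px, nt)
        return m.T.reshape(-1, ny, nx)


def casorati_svd(images: ParticleImageSequence) -> SvdDecomposition:
    """Thin SVD of the (pixels x frames) Casorati matrix."""
    frames = images.frames
    nf, ny, nx = frames.shape
    m = frames.reshape(nf, ny * nx).T  # pixels x frames
    u, s, vt = np.linalg.svd(m, full_matrices=False)
    return SvdDecomposition(
        singular_values=s,
        spatial=u.T.reshape(-1, ny, nx),
        temporal=vt,
        frame_shape=(ny, nx),
    )


def select_rank_thresholds(
    decomposition: SvdDecomposition,
    similarity_threshold: float = 0.3,
    low: Optional[int] = None,
    high: Optional[int] = None,
) -> Tuple[int, int]:
    """Semi-automatic rank thresholds from the spatial similarity matrix.

    The similarity of component i to the first component is the
    absolute Pearson correlation between the magnitudes of their
    spatial singular vectors.  The clutter subspace is the contiguous
    leading block of components whose similarity stays at or above
    ``similarity_threshold``; the low threshold is the size of that
    block.  When no component beyond the first correlates (no block
    structure), (1, rank) is returned with a warning.  The high
    threshold defaults to full rank.  Passing ``low``/``high``
    explicitly bypasses detection (manual override).

    Returns 1-based (low, high): components with index in (low, high]
    are retained by :func:`svd_filter`.
    """
    rank = decomposition.rank
    if low is not None and high is not None:
        return int(low), int(high)
    if rank < 3:
        raise ValueError("need rank >= 3 for threshold detection")

    mags = np.abs(decomposition.spatial.reshape(rank, -1))
    ref = mags[0]
    sims = np.empty(rank)
    sims[0] = 1.0
    for i in range(1, rank):
        c = np.corrcoef(ref, mags[i])[0, 1]
        sims[i] = abs(c) if np.isfinite(c) else 0.0
    below = np.nonzero(sims[1:] < similarity_threshold)[0]
    detected_low = int(below[0]) + 1 if below.size else rank - 1
    if detected_low <= 1:
        warnings.warn(
            "no clutter block structure detected in the similarity matrix; "
            "returning (1, rank)",
            stacklevel=2,
        )
        detected_low = 1
    return (detected_low if low is None else int(low),
            rank if high is None else int(high))


def svd_filter(
    images: ParticleImageSequence,
    low: int,
    high: Optional[int] = None,
    decomposition: Optional[SvdDecomposition] = None,
) -> ParticleImageSequence:
    """Reconstruct an image sequence from an SVD rank band.

    Components with 1-based index in (low, high] are retained; the
    first ``low`` components (clutter) and anything above ``high``
    (noise) are removed.  With ``low = 0`` and ``high = rank`` this is
    the identity to numerical precision.

    When ``decomposition`` is supplied, the filter acts as the linear
    projector onto that decomposition's selected spatial subspace, so
    filtering a sum of sequences equals the sum of filtered sequences.
    Otherwise the sequence's own SVD is used.
    """
    own = decomposition is None
    dec = casorati_svd(images) if own else decomposition
    rank = dec.rank
    if high is None:
        high = rank
    if not (0 <= low < high <= rank):
        raise ValueError(f"need 0 <= low < high <= rank ({rank}), got ({low}, {high})")

    if own:
        filtered = dec.reconstruct(low, high)
    else:
        ny, nx = dec.frame_shape
        u = dec.spatial[low:high].reshape(high - low, ny * nx).T
        m = images.frames.reshape(images.n_frames, ny * nx).T
        filtered = (u @ (u.T @ m)).T.reshape(-1, ny, nx)

    return ParticleImageSequence(
        frames=filtered,
        pixel_size=images.pixel_size,
        frame_rate=images.frame_rate,
        bit_depth=images.bit_depth,
        ground_truth=images.ground_truth,
        origin=images.origin,
    )
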