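"""Specificity-and-energy landscapes (SELs).

A SEL arranges every k-mer on concentric rings around a seed motif: ring h
holds the k-mers whose best alignment to the seed (over all offsets and,
optionally, the reverse complement) has exactly h mismatches.  Within a ring,
sequences are ordered deterministically — ring 0 by the position of the exact
match (5'-flanked sequences first) and rings h >= 1 by the tuple of mismatch
positions, then the substituted bases in alphabetical order, then offset,
then the flanking bases — so that two runs on the same profile produce
byte-identical layouts.  The radius equals the ring index and angles are
spread uniformly within each ring, which turns the table directly into the
familiar polar plot.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .selex import BindingProfile
from .seqcode import base_at, encode_strict, index_to_kmer, revcomp

ORIENTATIONS = ("forward", "reverse")


def best_match_distance(
    kmer: str, seed: str, use_rc: bool = True
) -> tuple[int, int, str]:
    """Minimum Hamming distance between the seed and any window of the k-mer.

    Windows of the reverse complement are searched too when ``use_rc``.
    Returns ``(mismatches, offset, orientation)``; ties prefer the smaller
    offset, then the forward orientation.
    """
    encode_strict(kmer)
    encode_strict(seed)
    k, m = len(kmer), len(seed)
    if m > k:
        raise ValueError("seed longer than k-mer")
    candidates = []
    strands = [("forward", kmer)] + ([("reverse", revcomp(kmer))] if use_rc else [])
    for oi, (orient, seq) in enumerate(strands):
        for off in range(k - m + 1):
            d = sum(a != b for a, b in zip(seq[off : off + m], seed))
            candidates.append((d, off, oi, orient))
    d, off, _, orient = min(candidates, key=lambda c: c[:3])
    return d, off, orient


@dataclass
class SELLayout:
    """Polar layout of all 4**k k-mers around a seed motif.

    Arrays are aligned with ``order`` (k-mer indices in display order); the
    radius of a row equals its ring.
    """

    seed: str
    k: int
    use_rc: bool
    order: np.ndarray  # k-mer index per display row
    ring: np.ndarray
    offset: np.ndarray
    orientation: np.ndarray  # 0 forward / 1 reverse
    index_in_ring: np.ndarray
    angle: np.ndarray
    csi: np.ndarray

    @property
    def n_rows(self) -> int:
        return self.order.shape[0]

    def ring_sizes(self) -> dict[int, int]:
        rings, counts = np.unique(self.ring, return_counts=True)
        return dict(zip(rings.tolist(), counts.tolist()))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kmer": [index_to_kmer(int(i), self.k) for i in self.order],
                "ring": self.ring,
                "index": self.index_in_ring,
                "angle": self.angle,
                "radius": self.ring.astype(float),
                "csi": self.csi,
            }
        )


def _alignment_arrays(k: int, seed_codes: np.ndarray, use_rc: bool):
    """Vectorized best alignment of every k-mer index against the seed.

    The candidate priority (distance, offset, forward-before-reverse) is
    encoded in a single integer rank so the minimum picks the stated
    tie-break.
    """
    m = seed_codes.shape[0]
    n = 4**k
    n_off = k - m + 1
    idx = np.arange(n, dtype=np.int64)
    best_rank = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    for off in range(n_off):
        for oi in range(2 if use_rc else 1):
            d = np.zeros(n, dtype=np.int64)
            for j in range(m):
                if oi == 0:
                    b = base_at(idx, off + j, k)
                else:
                    # window of revcomp(kmer) at `off` maps to complemented,
                    # mirrored positions of the k-mer itself
                    b = 3 - base_at(idx, k - 1 - off - j, k)
                d += b != seed_codes[j]
            rank = d * (2 * n_off) + off * 2 + oi
            np.minimum(best_rank, rank, out=best_rank)
    dist = best_rank // (2 * n_off)
    rem = best_rank % (2 * n_off)
    offset = rem // 2
    orient = rem % 2
    return dist, offset, orient


def _matched_window_base(idx, offset, orient, j, k):
    fwd = base_at(idx, offset + j, k)
    rev = 3 - base_at(idx, k - 1 - offset - j, k)
    return np.where(orient == 0, fwd, rev)


def build_layout(profile: BindingProfile, seed: str, use_rc: bool = True) -> SELLayout:
    """Place every k-mer of a profile on its mismatch ring around the seed."""
    seed_codes = encode_strict(seed)
    m = seed_codes.shape[0]
    k = profile.k
    if m > k:
        raise ValueError("seed longer than k")
    n = 4**k
    idx = np.arange(n, dtype=np.int64)
    dist, offset, orient = _alignment_arrays(k, seed_codes, use_rc)

    # sort keys, coarse to fine:
    #   ring; mismatch-position tuple (encoded so lexicographic tuple order is
    #   numeric); substituted bases (the matched window value itself, since
    #   non-mismatch positions equal the seed within a position class);
    #   offset (descending 5'-flank length in ring 0, ascending elsewhere);
    #   flanking bases of the oriented k-mer, 5' then 3'.
    mask = np.zeros(n, dtype=np.int64)
    window = np.zeros(n, dtype=np.int64)
    for j in range(m):
        b = _matched_window_base(idx, offset, orient, j, k)
        mask |= (b != seed_codes[j]).astype(np.int64) << (m - 1 - j)
        window = window * 4 + b
    mask_key = ((1 << m) - 1) - mask  # earliest-position tuples first

    flank = np.zeros(n, dtype=np.int64)
    for t in range(k - m):
        pos = np.where(t < offset, t, t + m)
        fwd = base_at(idx, pos, k)
        rev = 3 - base_at(idx, k - 1 - pos, k)
        flank = flank * 4 + np.where(orient == 0, fwd, rev)

    offset_key = np.where(dist == 0, (k - m) - offset, offset)
    order = np.lexsort((flank, offset_key, window, mask_key, dist))

    ring = dist[order]
    index_in_ring = np.empty(n, dtype=np.int64)
    angle = np.empty(n, dtype=float)
    # `order` is sorted by ring first, so rings form contiguous blocks
    boundaries = np.flatnonzero(np.diff(ring)) + 1
    for lo, hi in zip(
        np.concatenate(([0], boundaries)), np.concatenate((boundaries, [n]))
    ):
        size = hi - lo
        index_in_ring[lo:hi] = np.arange(size)
        angle[lo:hi] = 2.0 * np.pi * np.arange(size) / size

    return SELLayout(
        seed=seed,
        k=k,
        use_rc=use_rc,
        order=order,
        ring=ring,
        offset=offset[order],
        orientation=orient[order],
        index_in_ring=index_in_ring,
        angle=angle,
        csi=profile.csi[order],
    )


def choose_seed(profile: BindingProfile, mode: str = "top_kmer", given: str | None = None) -> str:
    """Seed motif for a SEL: the top-CSI k-mer, or a validated user seed."""
    if profile.n_kmers == 0:
        raise ValueError("empty profile")
    if mode == "top_kmer":
        return profile.top_kmer()
    if mode == "given":
        if given is None:
            raise ValueError("mode 'given' requires a seed string")
        encode_strict(given)
        if len(given) > profile.k:
            raise ValueError("seed longer than k")
        return given
    raise ValueError("mode must be 'top_kmer' or 'given'")


def export_layout(layout: SELLayout, path: str | Path, plot: str | Path | None = None) -> None:
    """Write the layout as TSV (kmer ring index angle radius csi).

    ``plot`` optionally renders a polar scatter (clockwise from 12 o'clock,
    intensity-colored) to the given image path.
    """
    df = layout.to_dataframe()
    df.to_csv(path, sep="\t", index=False)
    if plot is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig = plt.figure(figsize=(7, 7))
        ax = fig.add_subplot(projection="polar")
        ax.set_theta_zero_location("N")
        ax.set_theta_direction(-1)
        sc = ax.scatter(
            df["angle"], df["radius"], c=df["csi"], s=2, cmap="viridis", linewidths=0
        )
        fig.colorbar(sc, label="CSI intensity (z-score)")
        ax.set_title(f"SEL, seed {layout.seed}")
        fig.savefig(plot, dpi=150)
        plt.close(fig)


def read_layout(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
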