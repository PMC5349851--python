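"""SELEX-seq read processing and CSI intensity (k-mer z-score) profiles.

The cognate-site identification (CSI) intensity of a k-mer is the z-score of
its enrichment ratio in a selected sequencing round relative to the expected
count under a Markov background model fitted to the unselected starting
library (round 0):

    enrichment(w) = observed(w) / expected(w)
    csi(w)        = (enrichment(w) - mu) / sigma

with mu and sigma the mean and *population* standard deviation of the
enrichment values over all 4**k k-mers of one experiment.  The Markov model
(order 5 by default) absorbs synthesis and sequencing composition bias of the
random library.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .seqcode import (
    INVALID,
    encode,
    index_to_kmer,
    kmer_to_index,
    revcomp_index_table,
    window_indices,
)

logger = logging.getLogger(__name__)

STRAND_MODES = ("collapsed", "forward")


def _check_strand_mode(strand_mode: str) -> None:
    if strand_mode not in STRAND_MODES:
        raise ValueError(f"strand_mode must be one of {STRAND_MODES}, got {strand_mode!r}")


@dataclass
class ReadSet:
    """Uniform-length ACGT reads from one barcoded sample.

    Reads are stored as a ``(n, L)`` uint8 code matrix; round 0 marks the
    unselected starting library.
    """

    sample_id: str
    round: int
    codes: np.ndarray

    def __post_init__(self) -> None:
        if self.round < 0:
            raise ValueError("round must be >= 0")
        self.codes = np.atleast_2d(np.asarray(self.codes, dtype=np.uint8))
        if self.codes.size and np.any(self.codes > 3):
            raise ValueError("reads must contain only A/C/G/T")

    @classmethod
    def from_sequences(cls, sample_id: str, round: int, reads: Iterable[str]) -> "ReadSet":
        reads = list(reads)
        if not reads:
            raise ValueError("empty read list")
        L = len(reads[0])
        if any(len(r) != L for r in reads):
            raise ValueError("reads must all have the same length")
        codes = np.vstack([encode(r) for r in reads])
        if np.any(codes == INVALID):
            raise ValueError("reads must contain only A/C/G/T")
        return cls(sample_id, round, codes)

    @property
    def n_reads(self) -> int:
        return self.codes.shape[0]

    @property
    def read_len(self) -> int:
        return self.codes.shape[1]

    def sequences(self) -> list[str]:
        lut = np.frombuffer("ACGT".encode(), dtype=np.uint8)
        return [bytes(lut[row]).decode() for row in self.codes]


@dataclass
class MarkovModel:
    """Order-m background model of the starting library.

    ``initial`` is the position-pooled distribution of m-mers; ``transitions``
    has one row per m-mer context giving P(next base | context).  A positive
    pseudocount guarantees strictly positive probabilities, hence nonzero
    expected counts for every k-mer.
    """

    order: int
    initial: np.ndarray
    transitions: np.ndarray
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        n_ctx = 4**self.order
        if self.initial.shape != (n_ctx,):
            raise ValueError(f"initial must have shape ({n_ctx},)")
        if self.transitions.shape != (n_ctx, 4):
            raise ValueError(f"transitions must have shape ({n_ctx}, 4)")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-9):
            raise ValueError("initial probabilities must sum to 1")
        if not np.allclose(self.transitions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each transition row must sum to 1")


@dataclass
class DimerRecord:
    """Metadata for one homo- or heterodimer experiment.

    By convention the biotinylated partner (the one used for pull-down) is
    listed first in heterodimer names.  ``ppi_class`` records whether the pair
    dimerizes stably in solution (dissociation constant below 1 uM).
    """

    dimer_id: str
    monomer_a: str
    monomer_b: str
    biotinylated_partner: str
    ppi_class: str = "unknown"

    def __post_init__(self) -> None:
        if self.biotinylated_partner not in (self.monomer_a, self.monomer_b):
            raise ValueError("biotinylated_partner must be one of the monomers")
        if self.ppi_class not in ("stable", "unstable", "unknown"):
            raise ValueError("ppi_class must be stable/unstable/unknown")

    @property
    def is_homodimer(self) -> bool:
        return self.monomer_a == self.monomer_b


@dataclass
class BindingProfile:
    """Dense per-k-mer table for one dimer: counts, expectation, CSI z-score.

    All vectors have length 4**k and are indexed by the base-4 k-mer code.  In
    ``collapsed`` strand mode a k-mer and its reverse complement share one
    enrichment value, so csi(w) == csi(revcomp(w)) exactly.
    """

    dimer_id: str
    k: int
    strand_mode: str
    counts: np.ndarray
    expected: np.ndarray
    enrichment: np.ndarray
    csi: np.ndarray

    def __post_init__(self) -> None:
        _check_strand_mode(self.strand_mode)
        n = 4**self.k
        for name in ("counts", "expected", "enrichment", "csi"):
            v = np.asarray(getattr(self, name))
            if v.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
            setattr(self, name, v)

    @property
    def n_kmers(self) -> int:
        return 4**self.k

    def csi_of(self, kmer: str) -> float:
        return float(self.csi[kmer_to_index(kmer)])

    def top_kmer(self) -> str:
        # np.argmax returns the first (lexicographically smallest) maximum
        return index_to_kmer(int(np.argmax(self.csi)), self.k)

    def to_dataframe(self, n: int | None = None) -> pd.DataFrame:
        order = rank_order(self.csi)
        if n is not None:
            order = order[:n]
        return pd.DataFrame(
            {
                "kmer": [index_to_kmer(int(i), self.k) for i in order],
                "count": self.counts[order],
                "expected": self.expected[order],
                "enrichment": self.enrichment[order],
                "csi": self.csi[order],
            }
        )

    def replace(self, **kwargs) -> "BindingProfile":
        data = {
            "dimer_id": self.dimer_id,
            "k": self.k,
            "strand_mode": self.strand_mode,
            "counts": self.counts,
            "expected": self.expected,
            "enrichment": self.enrichment,
            "csi": self.csi,
        }
        data.update(kwargs)
        return BindingProfile(**data)


def rank_order(csi: np.ndarray) -> np.ndarray:
    """Indices sorted by csi descending, ties by lexicographic k-mer order."""
    n = csi.shape[0]
    return np.lexsort((np.arange(n), -csi))


@dataclass
class DemuxStats:
    retained: Counter = field(default_factory=Counter)
    discarded_too_short: int = 0
    discarded_barcode: int = 0
    discarded_ambiguous: int = 0


def demultiplex_and_trim(
    raw_reads: Iterable[str],
    barcode_map: Mapping[str, str],
    barcode_len: int = 6,
    insert_len: int = 20,
    sample_rounds: Mapping[str, int] | None = None,
) -> tuple[dict[str, ReadSet], DemuxStats]:
    """Assign raw reads to samples by exact barcode match and trim the insert.

    A read is kept only if it is long enough, its first ``barcode_len`` bases
    exactly match a barcode, and the ``insert_len`` bases that follow are pure
    ACGT; everything else is discarded and counted.  ``sample_rounds`` maps
    sample ids to selection rounds (default 0).
    """
    normalized = {b.upper(): s for b, s in barcode_map.items()}
    if len(normalized) != len(barcode_map):
        raise ValueError("duplicate barcode in map")
    if any(len(b) != barcode_len for b in normalized):
        raise ValueError(f"all barcodes must have length {barcode_len}")
    if len(set(normalized.values())) != len(normalized):
        raise ValueError("two barcodes map to the same sample_id")
    barcode_map = normalized

    stats = DemuxStats()
    per_sample: dict[str, list[str]] = {s: [] for s in barcode_map.values()}
    min_len = barcode_len + insert_len
    for read in raw_reads:
        if len(read) < min_len:
            stats.discarded_too_short += 1
            continue
        sample = barcode_map.get(read[:barcode_len])
        if sample is None:
            stats.discarded_barcode += 1
            continue
        insert = read[barcode_len : barcode_len + insert_len]
        if np.any(encode(insert) == INVALID):
            stats.discarded_ambiguous += 1
            continue
        per_sample[sample].append(insert)
        stats.retained[sample] += 1

    rounds = sample_rounds or {}
    out = {
        s: ReadSet.from_sequences(s, rounds.get(s, 0), reads)
        for s, reads in per_sample.items()
        if reads
    }
    for s, n in stats.retained.items():
        logger.info("demux: sample %s retained %d reads", s, n)
    logger.info(
        "demux: discarded %d short, %d barcode-mismatch, %d ambiguous",
        stats.discarded_too_short,
        stats.discarded_barcode,
        stats.discarded_ambiguous,
    )
    return out, stats


def count_kmers(readset: ReadSet, k: int, strand_mode: str = "collapsed") -> np.ndarray:
    """Sliding-window k-mer counts; each read yields L-k+1 forward windows.

    In ``collapsed`` mode every window also increments its reverse complement,
    so the count vector is strand-symmetric (and sums to twice the number of
    forward windows).
    """
    _check_strand_mode(strand_mode)
    if k > readset.read_len:
        raise ValueError(f"k={k} exceeds read length {readset.read_len}")
    idx, ok = window_indices(readset.codes, k)
    counts = np.bincount(idx[ok].ravel(), minlength=4**k).astype(np.int64)
    if strand_mode == "collapsed":
        counts = counts + counts[revcomp_index_table(k)]
    return counts


def fit_markov_background(
    round0: ReadSet, order: int = 5, pseudocount: float = 1.0
) -> MarkovModel:
    """Fit the order-m background model from the starting library (round 0).

    The initial distribution pools m-mer frequencies over all read positions
    (the model is stationary, not position-specific); transition rows are the
    smoothed conditional frequencies of each base given its preceding m-mer.
    Contexts never observed get a uniform row when pseudocount is 0.
    """
    if round0.round != 0:
        raise ValueError("background model must be fitted on round-0 reads")
    if order < 0:
        raise ValueError("order must be >= 0")
    if order >= round0.read_len:
        raise ValueError("order must be smaller than the read length")
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")

    n_ctx = 4**order
    if order == 0:
        init_counts = np.array([float(round0.n_reads * round0.read_len)])
    else:
        idx, ok = window_indices(round0.codes, order)
        init_counts = np.bincount(idx[ok].ravel(), minlength=n_ctx).astype(float)
    initial = init_counts + pseudocount
    initial /= initial.sum()

    idx1, ok1 = window_indices(round0.codes, order + 1)
    pair_counts = np.bincount(idx1[ok1].ravel(), minlength=4 ** (order + 1)).astype(float)
    trans = pair_counts.reshape(n_ctx, 4) + pseudocount
    row_sums = trans.sum(axis=1)
    empty = row_sums == 0
    if np.any(empty):
        trans[empty] = 0.25
        row_sums[empty] = 1.0
    trans /= row_sums[:, None]
    return MarkovModel(order=order, initial=initial, transitions=trans, pseudocount=pseudocount)


def expected_counts(model: MarkovModel, k: int, n_windows: int) -> np.ndarray:
    """Expected k-mer counts under the background model.

    Chain rule: P(w) = initial(w[:m]) * prod_i P(w[i] | w[i-m:i]); the vector
    of probabilities sums to 1 by construction and is scaled by ``n_windows``.
    """
    m = model.order
    if k <= m:
        raise ValueError(f"k must exceed the model order ({m})")
    p = model.initial.astype(float).copy()
    for ell in range(m, k):
        ctx = np.arange(4**ell, dtype=np.int64) % (4**m)
        p = (p[:, None] * model.transitions[ctx]).ravel()
    return n_windows * p


def compute_csi(
    observed: np.ndarray,
    expected: np.ndarray,
    strand_mode: str = "collapsed",
    dimer_id: str = "",
    zero_variance_eps: float = 1e-12,
) -> BindingProfile:
    """Build a BindingProfile: enrichment ratios z-standardized over all 4**k.

    In collapsed mode a k-mer is pooled with its reverse complement in both
    the observed and expected counts before taking the ratio, which makes the
    profile exactly strand-symmetric.  Standardization uses the population
    standard deviation (the 4**k table is the full population); an all-equal
    enrichment vector yields all-zero csi with a logged warning.
    """
    _check_strand_mode(strand_mode)
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError("observed and expected must cover the same k-mer space")
    n = observed.shape[0]
    k = round(np.log(n) / np.log(4))
    if 4**k != n:
        raise ValueError("table length must be a power of 4")
    if np.any(expected <= 0):
        raise ValueError(
            "expected counts must be strictly positive; fit the background "
            "model with a nonzero pseudocount"
        )

    if strand_mode == "collapsed":
        rc = revcomp_index_table(k)
        obs = observed + observed[rc]
        exp = expected + expected[rc]
    else:
        obs, exp = observed, expected
    enrichment = obs / exp
    mu = enrichment.mean()
    sigma = enrichment.std()  # population SD (ddof=0)
    if sigma < zero_variance_eps:
        logger.warning("zero enrichment variance for %s; csi set to 0", dimer_id or "<profile>")
        csi = np.zeros_like(enrichment)
    else:
        csi = (enrichment - mu) / sigma
    return BindingProfile(
        dimer_id=dimer_id,
        k=k,
        strand_mode=strand_mode,
        counts=observed,
        expected=expected,
        enrichment=enrichment,
        csi=csi,
    )


def profile_from_rounds(
    round0: ReadSet,
    enriched: ReadSet,
    k: int = 10,
    order: int = 5,
    pseudocount: float = 1.0,
    strand_mode: str = "collapsed",
    dimer_id: str | None = None,
) -> BindingProfile:
    """Full pipeline: background model from round 0, CSI from the enriched round."""
    model = fit_markov_background(round0, order=order, pseudocount=pseudocount)
    observed = count_kmers(enriched, k, strand_mode="forward")
    n_windows = enriched.n_reads * (enriched.read_len - k + 1)
    expected = expected_counts(model, k, n_windows)
    return compute_csi(
        observed,
        expected,
        strand_mode=strand_mode,
        dimer_id=dimer_id if dimer_id is not None else enriched.sample_id,
    )


def top_sequences(profile: BindingProfile, n: int) -> list[str]:
    """The n highest-CSI k-mers, ties broken lexicographically."""
    if not 1 <= n <= profile.n_kmers:
        raise ValueError(f"n must be in [1, {profile.n_kmers}]")
    order = rank_order(profile.csi)[:n]
    return [index_to_kmer(int(i), profile.k) for i in order]
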