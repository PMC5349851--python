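"""Comparison, clustering and assignment of dimer binding profiles.

Heterodimer SELEX experiments pull down the complex via one biotinylated
partner, so the recovered sequence preference may actually belong to that
partner's homodimer.  A profile is credited to the heterodimer only when it
is significantly less similar to the biotinylated homodimer's profile than
replicate experiments are to each other, or when the biotinylated partner
does not bind DNA as a homodimer at all.  Heterodimer motifs are classified
as conjoined (juxtaposed half-sites), variably spaced (overlapping
half-sites) or emergent (not derivable from either half-site).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy

from .selex import BindingProfile, top_sequences
from .seqcode import encode_strict, kmer_to_index, revcomp

logger = logging.getLogger(__name__)


def n_possible_dimers(n_monomers: int) -> int:
    """Number of distinct dimers (homo + hetero) formed by n monomers.

    Unordered pairs with repetition: n*(n+1)/2.
    """
    if n_monomers < 1:
        raise ValueError("need at least one monomer")
    return n_monomers * (n_monomers + 1) // 2


def enumerate_dimers(monomers: Sequence[str]) -> list[tuple[str, str]]:
    """All distinct dimer pairs (order-insensitive, homodimers included)."""
    if len(set(monomers)) != len(monomers):
        raise ValueError("monomer names must be unique")
    return list(itertools.combinations_with_replacement(monomers, 2))


def percentage(numerator: int, denominator: int) -> float:
    """Contingency-table percentage 100*numerator/denominator."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return 100.0 * numerator / denominator


@dataclass
class ComparisonSet:
    """Union of the top-n k-mers of several profiles, in deterministic order.

    In collapsed strand mode each reverse-complement pair is represented by
    its lexicographically smaller member.
    """

    kmers: list[str]
    n_per_dimer: int

    def __post_init__(self) -> None:
        if len(set(self.kmers)) != len(self.kmers):
            raise ValueError("comparison set contains duplicates")

    def __len__(self) -> int:
        return len(self.kmers)


def _canonical(kmer: str, collapsed: bool) -> str:
    return min(kmer, revcomp(kmer)) if collapsed else kmer


def build_comparison_set(profiles: Sequence[BindingProfile], n: int = 50) -> ComparisonSet:
    """Union of each profile's top-n distinct (canonical) k-mers.

    Order is deterministic: first appearance by profile order, then by rank
    within the profile.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    k = profiles[0].k
    mode = profiles[0].strand_mode
    if any(p.k != k for p in profiles):
        raise ValueError("profiles have mixed k")
    if any(p.strand_mode != mode for p in profiles):
        raise ValueError("profiles have mixed strand modes")
    collapsed = mode == "collapsed"

    out: list[str] = []
    seen: set[str] = set()
    for p in profiles:
        # in collapsed mode RC pairs tie and rank adjacently, so 2n+2 ranked
        # k-mers always contain n distinct canonical representatives
        ranked = top_sequences(p, min(p.n_kmers, 2 * n + 2))
        local: set[str] = set()
        for w in ranked:
            if len(local) == n:
                break
            c = _canonical(w, collapsed)
            if c in local:
                continue
            local.add(c)
            if c not in seen:
                seen.add(c)
                out.append(c)
    return ComparisonSet(kmers=out, n_per_dimer=n)


def _restricted_csi(profile: BindingProfile, cset: ComparisonSet) -> np.ndarray:
    idx = np.fromiter((kmer_to_index(w) for w in cset.kmers), dtype=np.int64)
    return profile.csi[idx]


def correlation_matrix(
    profiles: Sequence[BindingProfile], cset: ComparisonSet
) -> np.ndarray:
    """Pairwise Pearson r of CSI intensities restricted to the comparison set.

    Symmetric with unit diagonal; a profile with zero variance on the set
    yields NaN entries (recorded as missing).
    """
    if len(cset) < 3:
        raise ValueError("comparison set must contain at least 3 k-mers")
    vecs = np.vstack([_restricted_csi(p, cset) for p in profiles])
    sd = vecs.std(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = np.corrcoef(vecs)
    r[np.ix_(sd == 0, np.arange(len(profiles)))] = np.nan
    r[np.ix_(np.arange(len(profiles)), sd == 0)] = np.nan
    np.fill_diagonal(r, 1.0)
    return r


def cluster_dimers(matrix: np.ndarray, labels: Sequence[str] | None = None):
    """Hierarchical clustering of correlation-matrix rows.

    Euclidean distance between rows, complete linkage; missing entries are
    imputed as 0 with a warning.  Returns ``(linkage, leaf_order)``.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    if matrix.shape[0] < 2:
        raise ValueError("need at least two profiles to cluster")
    if np.isnan(matrix).any():
        logger.warning("correlation matrix has missing entries; imputing 0")
        matrix = np.nan_to_num(matrix, nan=0.0)
    Z = hierarchy.linkage(matrix, method="complete", metric="euclidean")
    leaf_order = list(hierarchy.leaves_list(Z))
    if labels is not None:
        leaf_order = [labels[i] for i in leaf_order]
    return Z, leaf_order


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string."""
    tree = hierarchy.to_tree(Z)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"


@dataclass
class AssignmentResult:
    """Verdict on whether a pulled-down profile belongs to the heterodimer."""

    dimer_id: str
    verdict: str  # heterodimer | homodimer | ambiguous | no_motif
    r_het_homo: float | None = None
    p_value: float | None = None


def assign_specificity(
    het_profile: BindingProfile,
    biotin_homo_profile: BindingProfile | None,
    replicate_rs: Sequence[float],
    cset: ComparisonSet,
    alpha: float = 0.05,
    motif_detected: bool = True,
) -> AssignmentResult:
    """Decide heterodimer vs biotinylated-homodimer origin of a profile.

    The heterodimer-vs-homodimer Pearson r (over the comparison set) is
    compared with the distribution of replicate-experiment correlations by a
    two-sided one-sample t-test on Fisher-z transformed values.  The profile
    is credited to the heterodimer when r is significantly below the
    replicate mean, to the homodimer when significantly above, and is
    ambiguous otherwise.  With no homodimer reference (the biotinylated
    partner binds no DNA on its own) the verdict is heterodimer outright.
    """
    if not motif_detected:
        return AssignmentResult(het_profile.dimer_id, "no_motif")
    if biotin_homo_profile is None:
        return AssignmentResult(het_profile.dimer_id, "heterodimer")
    if len(replicate_rs) < 2:
        logger.warning(
            "%s: fewer than 2 replicate correlations; verdict ambiguous",
            het_profile.dimer_id,
        )
        return AssignmentResult(het_profile.dimer_id, "ambiguous")

    x = _restricted_csi(het_profile, cset)
    y = _restricted_csi(biotin_homo_profile, cset)
    if x.std() == 0 or y.std() == 0:
        return AssignmentResult(het_profile.dimer_id, "ambiguous")
    r = float(np.corrcoef(x, y)[0, 1])

    clip = 1.0 - 1e-12
    z_reps = np.arctanh(np.clip(np.asarray(replicate_rs, dtype=float), -clip, clip))
    z_r = float(np.arctanh(np.clip(r, -clip, clip)))
    t = stats.ttest_1samp(z_reps, popmean=z_r)
    p = float(t.pvalue)

    if p < alpha and r < float(np.mean(replicate_rs)):
        verdict = "heterodimer"
    elif p < alpha:
        verdict = "homodimer"
    else:
        verdict = "ambiguous"
    return AssignmentResult(het_profile.dimer_id, verdict, r_het_homo=r, p_value=p)


def score_site(profile: BindingProfile, site: str) -> float:
    """Maximum CSI over all k-mers containing ``site`` as a substring.

    In collapsed mode the reverse complement of the site is matched as well
    (equivalent by strand symmetry of the profile).
    """
    codes = encode_strict(site)
    s = len(codes)
    k = profile.k
    if s > k:
        raise ValueError(f"site length {s} exceeds k={k}")
    sites = [site]
    if profile.strand_mode == "collapsed":
        sites.append(revcomp(site))
    best = -np.inf
    for sequence in set(sites):
        site_idx = kmer_to_index(sequence)
        for off in range(k - s + 1):
            suf_len = k - s - off
            pre = np.arange(4**off, dtype=np.int64)
            suf = np.arange(4**suf_len, dtype=np.int64)
            idx = ((pre[:, None] * 4**s + site_idx) * 4**suf_len + suf[None, :]).ravel()
            best = max(best, float(profile.csi[idx].max()))
    return best


@dataclass
class MotifArchitecture:
    """Classification of a heterodimer motif relative to two half-sites."""

    klass: str  # conjoined | variably_spaced | emergent
    half_a: str
    half_b: str
    overlap: int
    matched_kmer: str


def _merged_arrangements(half_a: str, half_b: str, overlap: int) -> Iterable[str]:
    """All half-site arrangements at a given overlap.

    Both orders and both orientations of each half-site are enumerated; an
    overlap requires the shared bases to agree exactly.
    """
    variants_a = {half_a, revcomp(half_a)}
    variants_b = {half_b, revcomp(half_b)}
    for x, y in itertools.chain(
        itertools.product(variants_a, variants_b),
        itertools.product(variants_b, variants_a),
    ):
        if overlap == 0:
            yield x + y
        elif overlap < min(len(x), len(y)) and x[-overlap:] == y[:overlap]:
            yield x + y[overlap:]


def classify_architecture(
    het_top_kmer: str,
    half_a: str,
    half_b: str,
    max_overlap: int = 3,
) -> MotifArchitecture:
    """Classify a heterodimer's top k-mer as conjoined/variably-spaced/emergent.

    If any zero-overlap juxtaposition of the half-sites occurs within the
    k-mer (either strand) the motif is conjoined; otherwise the smallest
    overlap in [1, max_overlap] with agreeing shared bases that occurs wins
    (variably spaced); otherwise the site is emergent.
    """
    encode_strict(het_top_kmer)
    for h in (half_a, half_b):
        encode_strict(h)
        if not 3 <= len(h) <= 5:
            raise ValueError("half-sites must be 3-5 bp")
        if len(h) > len(het_top_kmer):
            raise ValueError("half-site longer than the k-mer")
    targets = (het_top_kmer, revcomp(het_top_kmer))
    for overlap in range(0, max_overlap + 1):
        for merged in _merged_arrangements(half_a, half_b, overlap):
            if len(merged) <= len(het_top_kmer) and any(merged in t for t in targets):
                klass = "conjoined" if overlap == 0 else "variably_spaced"
                return MotifArchitecture(klass, half_a, half_b, overlap, merged)
    return MotifArchitecture("emergent", half_a, half_b, 0, het_top_kmer)
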