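"""Synthetic SELEX libraries, selections, genomes and variant panels.

The generator provides ground-truth inputs for every pipeline stage: a
randomized 20-bp library (optionally with synthesis bias), multi-round
selections driven by planted dimer site models, genomes with planted
high-affinity peaks, and SNP panels that create, destroy or spare sites.

Selection model.  A dimer is summarized by one cognate site (built from its
half-sites, or given outright for emergent binders) and a geometric affinity
decay: affinity(read) = peak_affinity * mismatch_decay ** d, with d the
minimum Hamming distance between the site and any read window on either
strand.  The per-round retention weight is max(1, affinity) — occupancy
cannot drop below the nonspecific background, which is normalized to 1.
A truth with peak_affinity = 1 therefore selects nothing (the null case).

Because the physical library (~1e12 molecules) is astronomically larger
than a sequencing sample, sequenced reads are essentially never siblings.
Each round r is therefore sampled by exact importance reweighting of the
synthesis distribution: fresh candidate reads are drawn from the library
model, resampled with weight w(read)**r, and the bases outside the matched
site window are re-randomized so that selected molecules are distinct, as
they would be in the real pool.  Under the null this reproduces the round-0
spectrum exactly; under selection the planted-site classes enrich with the
correct multiplicative per-round factors.  A uniform capture efficiency
multiplies every molecule's retention probability and cancels under
normalization, so ``capture_fraction`` is recorded in the provenance but
does not alter the sampled distributions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genomescape import GenomicInterval
from .selex import MarkovModel, ReadSet
from .seqcode import BASES, encode_strict, revcomp
from .snp import SNPRecord

logger = logging.getLogger(__name__)

MODES = ("homodimer", "conjoined", "variably_spaced", "emergent")


@dataclass
class GroundTruthDimer:
    """Ground-truth site model for one simulated dimer.

    The full cognate site derives from the mode: homodimers bind the
    palindrome half_a + revcomp(half_a); conjoined heterodimers juxtapose
    half_a and half_b; variably-spaced heterodimers overlap them by
    ``overlap`` agreeing bases; emergent heterodimers bind ``emergent_site``
    outright.
    """

    dimer_id: str
    mode: str
    half_a: str = ""
    half_b: str = ""
    overlap: int = 0
    emergent_site: str = ""
    peak_affinity: float = 500.0
    mismatch_decay: float = 0.2

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if not 0 < self.mismatch_decay < 1:
            raise ValueError("mismatch_decay must be in (0, 1)")
        if self.peak_affinity < 1:
            raise ValueError("peak_affinity must be >= 1")
        for h in filter(None, (self.half_a, self.half_b)):
            encode_strict(h)
            if not 3 <= len(h) <= 5:
                raise ValueError("half-sites must be 3-5 bp")
        _ = self.site  # validate mode-specific requirements eagerly

    @property
    def site(self) -> str:
        if self.mode == "homodimer":
            if not self.half_a:
                raise ValueError("homodimer requires half_a")
            return self.half_a + revcomp(self.half_a)
        if self.mode == "conjoined":
            if not (self.half_a and self.half_b):
                raise ValueError("conjoined requires both half-sites")
            return self.half_a + self.half_b
        if self.mode == "variably_spaced":
            if not (self.half_a and self.half_b):
                raise ValueError("variably_spaced requires both half-sites")
            if not 1 <= self.overlap <= 3:
                raise ValueError("variably_spaced overlap must be in [1, 3]")
            if self.half_a[-self.overlap :] != self.half_b[: self.overlap]:
                raise ValueError("overlapping bases of the half-sites must agree")
            return self.half_a + self.half_b[self.overlap :]
        if not self.emergent_site:
            raise ValueError("emergent mode requires emergent_site")
        encode_strict(self.emergent_site)
        return self.emergent_site

    def affinity(self, mismatches: np.ndarray | int) -> np.ndarray | float:
        """Strictly decreasing in the mismatch count."""
        return self.peak_affinity * self.mismatch_decay ** np.asarray(mismatches, dtype=float)


@dataclass
class SimulationConfig:
    n_reads: int = 100_000
    read_len: int = 20
    rounds: int = 3
    library_bias: MarkovModel | None = None  # None = uniform synthesis
    capture_fraction: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1 or self.read_len < 1 or self.rounds < 1:
            raise ValueError("n_reads, read_len and rounds must be positive")
        if not 0 < self.capture_fraction < 1:
            raise ValueError("capture_fraction must be in (0, 1)")

    def provenance(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "read_len": self.read_len,
            "rounds": self.rounds,
            "library_bias": "uniform"
            if self.library_bias is None
            else f"markov_order_{self.library_bias.order}",
            "capture_fraction": self.capture_fraction,
            "rng_seed": self.rng_seed,
        }

    def write_provenance(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.provenance(), indent=2) + "\n")


def _rng(config: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.rng_seed, *stream]))


def _base_marginal(model: MarkovModel | None) -> np.ndarray:
    """Single-base marginal of the library model (uniform when model is None)."""
    if model is None:
        return np.full(4, 0.25)
    m = model.order
    if m == 0:
        return model.transitions[0].copy()
    # average base composition of the initial m-mer distribution
    marg = np.zeros(4)
    idx = np.arange(4**m)
    for pos in range(m):
        b = (idx >> (2 * (m - 1 - pos))) & 3
        for base in range(4):
            marg[base] += model.initial[b == base].sum()
    return marg / m


def _sample_codes(
    model: MarkovModel | None, n: int, L: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample n reads of length L from the library model."""
    if model is None:
        return rng.integers(0, 4, size=(n, L), dtype=np.uint8)
    m = model.order
    codes = np.empty((n, L), dtype=np.uint8)
    if m == 0:
        ctx = np.zeros(n, dtype=np.int64)
        start = 0
    else:
        start = min(m, L)
        init_idx = rng.choice(4**m, size=n, p=model.initial)
        for pos in range(start):
            codes[:, pos] = (init_idx >> (2 * (m - 1 - pos))) & 3
        ctx = init_idx % (4**m) if start == m else init_idx
        if start < m:  # reads shorter than the order: truncate and stop
            return codes
    cum = np.cumsum(model.transitions, axis=1)
    for pos in range(start, L):
        r = rng.random(n)
        codes[:, pos] = (r[:, None] > cum[ctx]).sum(axis=1).astype(np.uint8)
        ctx = (ctx * 4 + codes[:, pos]) % (4**m) if m > 0 else ctx
    return codes


def simulate_library(config: SimulationConfig) -> ReadSet:
    """Round-0 starting library drawn from the synthesis model."""
    rng = _rng(config, 0)
    codes = _sample_codes(config.library_bias, config.n_reads, config.read_len, rng)
    return ReadSet(sample_id="library", round=0, codes=codes)


def _best_site_match(codes: np.ndarray, site: str) -> tuple[np.ndarray, np.ndarray]:
    """Per read: (min mismatches, window start) of the site on either strand."""
    sc_f = encode_strict(site)
    sc_r = encode_strict(revcomp(site))
    n, L = codes.shape
    s = sc_f.shape[0]
    if s > L:
        raise ValueError("site longer than the reads")
    n_off = L - s + 1
    best = np.full(n, np.iinfo(np.int32).max, dtype=np.int32)
    for strand, sc in enumerate((sc_f, sc_r)):
        for off in range(n_off):
            d = (codes[:, off : off + s] != sc).sum(axis=1, dtype=np.int32)
            rank = d * (2 * n_off) + off * 2 + strand
            np.minimum(best, rank, out=best)
    dist = best // (2 * n_off)
    offset = (best % (2 * n_off)) // 2
    return dist, offset


def simulate_selex(
    library: ReadSet,
    truth: Sequence[GroundTruthDimer] | GroundTruthDimer,
    config: SimulationConfig,
) -> list[ReadSet]:
    """Rounds 1..R of selection for one dimer (possibly with several sites).

    Each round is an independent exact sample of the selected distribution
    p_r ∝ p0(read) * max(1, affinity(read))**r; see the module docstring.
    """
    truths = [truth] if isinstance(truth, GroundTruthDimer) else list(truth)
    if library.n_reads == 0:
        raise ValueError("library is empty")
    if not truths:
        raise ValueError("need at least one ground-truth site model")
    n, L = config.n_reads, library.read_len
    marginal = _base_marginal(config.library_bias)
    out: list[ReadSet] = []
    for r in range(1, config.rounds + 1):
        rng = _rng(config, 1, r)
        cand = _sample_codes(config.library_bias, n, L, rng)
        aff = np.zeros(n)
        off_win = np.zeros(n, dtype=np.int64)
        len_win = np.zeros(n, dtype=np.int64)
        for t in truths:
            d_t, off_t = _best_site_match(cand, t.site)
            aff_t = t.affinity(d_t)
            better = aff_t > aff
            aff = np.where(better, aff_t, aff)
            off_win = np.where(better, off_t, off_win)
            len_win = np.where(better, len(t.site), len_win)
        w = np.maximum(1.0, aff) ** r
        if aff.max() <= 1.0 and w.max() == w.min():
            logger.warning("round %d: no affinity signal; sampling uniformly", r)
        sel = rng.choice(n, size=n, replace=True, p=w / w.sum())
        codes = cand[sel]
        # selected molecules are distinct in the real pool: specifically bound
        # molecules (affinity above the nonspecific floor) keep their matched
        # site window with everything else refreshed from the synthesis
        # marginal; baseline-weight molecules are exchangeable background and
        # become entirely fresh draws
        cols = np.arange(L)
        specific = (aff[sel] > 1.0)[:, None]
        keep = (
            specific
            & (cols >= off_win[sel, None])
            & (cols < (off_win[sel] + len_win[sel])[:, None])
        )
        fresh = rng.choice(4, size=(n, L), p=marginal).astype(np.uint8)
        codes = np.where(keep, codes, fresh)
        out.append(ReadSet(sample_id=f"{library.sample_id}_round{r}", round=r, codes=codes))
    return out


@dataclass
class PlantedSite:
    dimer_id: str
    start: int  # 0-based
    strand: str  # + / -
    sequence: str  # the oriented site string as written into the genome


@dataclass
class SyntheticGenome:
    sequences: dict[str, str]
    sites: list[PlantedSite] = field(default_factory=list)
    peaks: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    chrom: str = "chrS"

    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


def simulate_genome_and_peaks(
    truth: Sequence[GroundTruthDimer] | GroundTruthDimer,
    genome_len: int,
    n_sites: int,
    config: SimulationConfig,
    peak_halfwidth: int = 100,
    chrom: str = "chrS",
) -> SyntheticGenome:
    """Background genome with planted full-length sites and truth peaks.

    Sites are planted on an evenly spaced grid with random jitter and random
    strand, one peak of +/- ``peak_halfwidth`` bp per site.  Jitter keeps
    sites (and hence peaks) non-overlapping by construction.
    """
    truths = [truth] if isinstance(truth, GroundTruthDimer) else list(truth)
    total = n_sites * len(truths)
    slot = genome_len // (total + 1)
    max_site = max(len(t.site) for t in truths)
    if slot < 4 * peak_halfwidth + max_site:
        raise ValueError("genome too short for the requested number of sites")
    rng = _rng(config, 2)
    codes = rng.choice(4, size=genome_len, p=_base_marginal(config.library_bias)).astype(np.uint8)
    lut = np.frombuffer(BASES.encode(), dtype=np.uint8)

    sites: list[PlantedSite] = []
    peaks: dict[str, list[GenomicInterval]] = {t.dimer_id: [] for t in truths}
    order = [t for t in truths for _ in range(n_sites)]
    for i, t in enumerate(order):
        site = t.site
        lo = (i + 1) * slot - slot // 4
        hi = (i + 1) * slot + slot // 4 - len(site)
        start = int(rng.integers(lo, hi))
        strand = "+" if rng.random() < 0.5 else "-"
        oriented = site if strand == "+" else revcomp(site)
        codes[start : start + len(site)] = encode_strict(oriented)
        sites.append(PlantedSite(t.dimer_id, start, strand, oriented))
        center = start + len(site) // 2
        peaks[t.dimer_id].append(
            GenomicInterval(
                chrom,
                max(0, center - peak_halfwidth),
                min(genome_len, center + peak_halfwidth),
                name=f"{t.dimer_id}_site{len(peaks[t.dimer_id])}",
            )
        )
    sequence = bytes(lut[codes]).decode()
    return SyntheticGenome(sequences={chrom: sequence}, sites=sites, peaks=peaks, chrom=chrom)


def simulate_snp_panel(
    genome: SyntheticGenome | None,
    truth: Sequence[GroundTruthDimer] | GroundTruthDimer,
    n_create: int,
    n_destroy: int,
    n_neutral: int,
    config: SimulationConfig,
    spacing: int = 100,
    chrom: str = "chr_snp",
) -> tuple[SyntheticGenome, list[SNPRecord], pd.DataFrame]:
    """Variant panel with known effects on planted sites.

    The panel lives on its own chromosome (appended to ``genome`` when one is
    given).  Create-variants plant a site carrying one core mismatch whose
    alternate allele restores the full site; destroy-variants plant the full
    site and break one core position; neutral variants mutate plain
    background at least a site length away from anything planted.  Returns
    the augmented genome, the SNP records, and a truth-label table.
    """
    truths = [truth] if isinstance(truth, GroundTruthDimer) else list(truth)
    total = n_create + n_destroy + n_neutral
    if total < 1:
        raise ValueError("empty panel requested")
    max_site = max(len(t.site) for t in truths)
    if spacing < 2 * max_site + 22:
        raise ValueError("spacing too small to isolate variants from sites")
    rng = _rng(config, 3)
    length = spacing * (total + 2)
    codes = rng.choice(4, size=length, p=_base_marginal(config.library_bias)).astype(np.uint8)
    lut = np.frombuffer(BASES.encode(), dtype=np.uint8)

    labels = (["create"] * n_create) + (["destroy"] * n_destroy) + (["neutral"] * n_neutral)
    snps: list[SNPRecord] = []
    rows = []
    planted: list[PlantedSite] = []
    for i, label in enumerate(labels):
        t = truths[i % len(truths)]
        site = t.site
        start = spacing * (i + 1)
        strand = "+" if rng.random() < 0.5 else "-"
        oriented = site if strand == "+" else revcomp(site)
        site_codes = encode_strict(oriented)
        j = int(rng.integers(0, len(site)))  # mutated core position
        site_base = oriented[j]
        other = [b for b in BASES if b != site_base]
        mismatch_base = other[int(rng.integers(0, 3))]

        if label == "neutral":
            pos0 = start
            ref = BASES[codes[pos0]]
            alt = [b for b in BASES if b != ref][int(rng.integers(0, 3))]
        else:
            codes[start : start + len(site)] = site_codes
            planted.append(PlantedSite(t.dimer_id, start, strand, oriented))
            pos0 = start + j
            if label == "create":
                # genome carries the broken site; the alternate allele fixes it
                codes[pos0] = encode_strict(mismatch_base)[0]
                ref, alt = mismatch_base, site_base
            else:
                ref, alt = site_base, mismatch_base
        snp = SNPRecord(
            id=f"syn{i}", chrom=chrom, pos=pos0 + 1, ref=ref, alt=alt, trait=label
        )
        snps.append(snp)
        rows.append(
            {"snp_id": snp.id, "label": label, "dimer_id": "" if label == "neutral" else t.dimer_id}
        )

    sequence = bytes(lut[codes]).decode()
    if genome is None:
        out = SyntheticGenome(sequences={chrom: sequence}, sites=planted, chrom=chrom)
    else:
        sequences = dict(genome.sequences)
        if chrom in sequences:
            raise ValueError(f"genome already has a chromosome named {chrom}")
        sequences[chrom] = sequence
        out = SyntheticGenome(
            sequences=sequences,
            sites=genome.sites + planted,
            peaks=genome.peaks,
            chrom=genome.chrom,
        )
    return out, snps, pd.DataFrame(rows)
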