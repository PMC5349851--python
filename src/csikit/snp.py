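"""Allele scoring of noncoding SNPs with CSI profiles.

Each variant is scored on the 21-bp context centered on the SNP (10 bp of
flank per side): both alleles receive the maximum CSI intensity over the
twelve 10-bp windows of their context, and the predicted binding change is a
noise-buffered fold-change

    FC = (z_alt - z_min + A) / (z_ref - z_min + A),   A = (z_max - z_min) * F

where z_min / z_max span the allele scores of the scanned SNP set (per dimer
by default) and the noise factor F — a fraction of the CSI dynamic range —
damps instability at low scores.  FC >= threshold marks a predicted gain of
binding relative to the reference genome, FC <= 1/threshold a loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomescape import score_interval
from .selex import BindingProfile
from .seqcode import BASES

logger = logging.getLogger(__name__)


class ReferenceMismatchError(ValueError):
    """The genome base at a SNP position does not match the declared ref allele."""


@dataclass(frozen=True)
class SNPRecord:
    """A single-base substitution with 1-based (VCF-style) coordinates."""

    id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    trait: str = ""

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(
                f"{self.id}: only single-base substitutions are supported "
                "(indels are rejected)"
            )
        if self.ref.upper() not in BASES or self.alt.upper() not in BASES:
            raise ValueError(f"{self.id}: alleles must be A/C/G/T")
        if self.ref.upper() == self.alt.upper():
            raise ValueError(f"{self.id}: ref and alt alleles are identical")


@dataclass
class SNPImpact:
    snp_id: str
    dimer_id: str
    z_ref: float
    z_alt: float
    fold_change: float
    noise_factor: float
    buffer: float  # A = (z_max - z_min) * F


def allele_contexts(
    genome: Mapping[str, object], snp: SNPRecord, flank: int = 10
) -> tuple[str, str] | None:
    """Reference and alternate 2*flank+1 bp contexts centered on the SNP.

    Returns None (with a warning) when the SNP sits closer than ``flank`` to
    a chromosome end; raises :class:`ReferenceMismatchError` when the genome
    disagrees with the declared reference allele.
    """
    seq_obj = genome[snp.chrom]
    chrom_len = len(seq_obj)
    start0 = snp.pos - 1 - flank  # 0-based start of the context
    if start0 < 0 or snp.pos + flank > chrom_len:
        logger.warning("%s: closer than %d bp to a chromosome end; skipped", snp.id, flank)
        return None
    ref_seq = str(seq_obj[start0 : start0 + 2 * flank + 1]).upper()
    if ref_seq[flank] != snp.ref.upper():
        raise ReferenceMismatchError(
            f"{snp.id}: genome has {ref_seq[flank]} at {snp.chrom}:{snp.pos}, "
            f"expected ref allele {snp.ref}"
        )
    alt_seq = ref_seq[:flank] + snp.alt.upper() + ref_seq[flank + 1 :]
    return ref_seq, alt_seq


def score_allele(context: str, profile: BindingProfile) -> float:
    """Max CSI over the sliding k-mer windows of one allele's context.

    A 21-bp context scored with a 10-mer profile is evaluated on exactly
    twelve windows; collapsed-strand profiles cover both orientations.
    """
    if len(context) < profile.k:
        raise ValueError(
            f"context length {len(context)} shorter than k={profile.k}"
        )
    max_csi, _ = score_interval(context, profile)
    return max_csi


def allele_track(context: str, profile: BindingProfile) -> np.ndarray:
    """Per-window CSI track of a context (for genomescape-style panels)."""
    _, track = score_interval(context, profile)
    return track


def fold_change(
    z_ref: float, z_alt: float, z_min: float, z_max: float, noise_factor: float
) -> float:
    """Noise-buffered allele fold-change.

    ``noise_factor`` is the fraction of the CSI dynamic range added to both
    numerator and denominator (the percent convention F = 25 corresponds to
    noise_factor = 0.25).  Swapping ref and alt maps the result to its
    reciprocal exactly.
    """
    if z_max <= z_min:
        raise ValueError("z_max must exceed z_min")
    if noise_factor <= 0:
        raise ValueError("noise_factor must be positive")
    a = (z_max - z_min) * noise_factor
    return (z_alt - z_min + a) / (z_ref - z_min + a)


@dataclass
class SNPScanResult:
    z_ref: pd.DataFrame  # SNPs x dimers
    z_alt: pd.DataFrame
    fold_changes: pd.DataFrame
    hits: pd.DataFrame  # snp_id, dimer_id, z_ref, z_alt, fold_change, direction
    z_range: pd.DataFrame  # per dimer: z_min, z_max, buffer A
    skipped: list[str]


def snp_scan(
    snps: Sequence[SNPRecord],
    profiles: Sequence[BindingProfile],
    genome: Mapping[str, object],
    noise_factor: float = 0.25,
    threshold: float = 2.0,
    flank: int = 10,
    minmax_scope: str = "per_dimer",
) -> SNPScanResult:
    """Score ref/alt alleles of all SNPs under all profiles and call hits.

    z_min / z_max are taken over all allele scores of the scanned set —
    per dimer by default, or globally across dimers with
    ``minmax_scope="global"``.  A dimer whose allele scores are all equal
    yields no hits (the fold-change is defined as 1).  Ordering follows the
    input SNP and profile order.
    """
    if not snps:
        raise ValueError("empty SNP list")
    if minmax_scope not in ("per_dimer", "global"):
        raise ValueError("minmax_scope must be 'per_dimer' or 'global'")
    if any(p.k != profiles[0].k for p in profiles):
        raise ValueError("profiles have mixed k")
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")

    kept: list[SNPRecord] = []
    contexts: list[tuple[str, str]] = []
    skipped: list[str] = []
    for snp in snps:
        ctx = allele_contexts(genome, snp, flank=flank)
        if ctx is None:
            skipped.append(snp.id)
        else:
            kept.append(snp)
            contexts.append(ctx)
    if not kept:
        raise ValueError("all SNPs were skipped (chromosome-end bounds)")

    dimer_ids = [p.dimer_id for p in profiles]
    snp_ids = [s.id for s in kept]
    zr = np.empty((len(kept), len(profiles)))
    za = np.empty_like(zr)
    for j, prof in enumerate(profiles):
        for i, (ref_seq, alt_seq) in enumerate(contexts):
            zr[i, j] = score_allele(ref_seq, prof)
            za[i, j] = score_allele(alt_seq, prof)

    if minmax_scope == "global":
        z_min = np.full(len(profiles), min(np.nanmin(zr), np.nanmin(za)))
        z_max = np.full(len(profiles), max(np.nanmax(zr), np.nanmax(za)))
    else:
        z_min = np.minimum(np.nanmin(zr, axis=0), np.nanmin(za, axis=0))
        z_max = np.maximum(np.nanmax(zr, axis=0), np.nanmax(za, axis=0))

    fc = np.ones_like(zr)
    buffers = np.zeros(len(profiles))
    for j in range(len(profiles)):
        if z_max[j] <= z_min[j]:
            logger.warning(
                "%s: no dynamic range among scored alleles; no hits", dimer_ids[j]
            )
            continue
        buffers[j] = (z_max[j] - z_min[j]) * noise_factor
        fc[:, j] = (za[:, j] - z_min[j] + buffers[j]) / (zr[:, j] - z_min[j] + buffers[j])

    hit_rows = []
    for i, snp in enumerate(kept):
        for j, d in enumerate(dimer_ids):
            if fc[i, j] >= threshold or fc[i, j] <= 1.0 / threshold:
                hit_rows.append(
                    {
                        "snp_id": snp.id,
                        "dimer_id": d,
                        "trait": snp.trait,
                        "z_ref": zr[i, j],
                        "z_alt": za[i, j],
                        "fold_change": fc[i, j],
                        "direction": "gain" if fc[i, j] >= threshold else "loss",
                    }
                )
    hits = pd.DataFrame(
        hit_rows,
        columns=["snp_id", "dimer_id", "trait", "z_ref", "z_alt", "fold_change", "direction"],
    )
    z_range = pd.DataFrame(
        {"z_min": z_min, "z_max": z_max, "buffer": buffers}, index=dimer_ids
    )
    return SNPScanResult(
        z_ref=pd.DataFrame(zr, index=snp_ids, columns=dimer_ids),
        z_alt=pd.DataFrame(za, index=snp_ids, columns=dimer_ids),
        fold_changes=pd.DataFrame(fc, index=snp_ids, columns=dimer_ids),
        hits=hits,
        z_range=z_range,
        skipped=skipped,
    )
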