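"""End-to-end recovery studies on synthetic ground truth.

These runners exercise the whole pipeline — library synthesis, multi-round
selection, CSI profiling, motif-architecture classification, genomescape
ROC analysis, and SNP impact scanning — against planted truth, and report
recovery rates.  They are used by the test suite and by the reproduction
script; the study sizes (20 seeded runs, 1e5 reads, 3 selection rounds)
are the package's reference conditions for desk-scale validation.

Site models reuse motifs of the bZIP literature: the conjoined CRE-CAAT
site TGACGCAA, the variably-spaced TRE-CAAT site TGAGCAA (half-sites
sharing one base), and the emergent site TGACGCAT, whose parent homodimers
bind CRE-style palindromes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .compare import classify_architecture
from .genomescape import flank_negatives, roc_curve, score_interval
from .selex import BindingProfile, profile_from_rounds
from .seqcode import revcomp
from .simulate import (
    GroundTruthDimer,
    SimulationConfig,
    simulate_genome_and_peaks,
    simulate_library,
    simulate_selex,
    simulate_snp_panel,
)
from .snp import snp_scan

HET_TRUTHS = {
    "conjoined": GroundTruthDimer(
        dimer_id="het_conjoined", mode="conjoined", half_a="TGAC", half_b="GCAA"
    ),
    "variably_spaced": GroundTruthDimer(
        dimer_id="het_spaced", mode="variably_spaced", half_a="TGAG", half_b="GCAA", overlap=1
    ),
    "emergent": GroundTruthDimer(
        dimer_id="het_emergent",
        mode="emergent",
        half_a="TGAC",
        half_b="GTCA",
        emergent_site="TGACGCAT",
    ),
}

PARENT_TRUTHS = (
    GroundTruthDimer(dimer_id="homo_a", mode="homodimer", half_a="TGAC"),
    GroundTruthDimer(dimer_id="homo_b", mode="homodimer", half_a="GTCA"),
)


def derive_seed(base_seed: int, *stream: int) -> int:
    """Stable sub-seed below 2**31 from a base seed and a stream label."""
    ss = np.random.SeedSequence([int(base_seed), *map(int, stream)])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_profile(
    truth: GroundTruthDimer | list[GroundTruthDimer],
    seed: int,
    n_reads: int = 100_000,
    rounds: int = 3,
    k: int = 10,
    order: int = 5,
) -> BindingProfile:
    """Library + selection + CSI profile for one dimer, one seed."""
    config = SimulationConfig(n_reads=n_reads, rounds=rounds, rng_seed=seed)
    library = simulate_library(config)
    selected = simulate_selex(library, truth, config)
    first = truth[0] if isinstance(truth, list) else truth
    return profile_from_rounds(
        library, selected[-1], k=k, order=order, dimer_id=first.dimer_id
    )


def site_recovered(profile: BindingProfile, site: str) -> bool:
    """Does the argmax-CSI k-mer contain the planted site (either strand)?"""
    top = profile.top_kmer()
    return site in top or revcomp(site) in top


@dataclass
class RecoveryStudy:
    """Aggregated results of the seeded end-to-end recovery runs."""

    n_runs: int
    recovery: dict[str, float] = field(default_factory=dict)  # mode -> % runs
    classification: dict[str, float] = field(default_factory=dict)  # mode -> % runs
    het_aucs: list[float] = field(default_factory=list)
    parent_aucs: list[tuple[float, float]] = field(default_factory=list)
    pct_het_auc_above_0_9: float = float("nan")
    pct_het_auc_above_parents: float = float("nan")
    pct_create_snps_gained: float = float("nan")
    pct_neutral_snps_quiet: float = float("nan")


def run_motif_recovery(
    base_seed: int, n_runs: int = 20, n_reads: int = 100_000, rounds: int = 3
) -> RecoveryStudy:
    """Planted-site recovery and architecture classification, per mode."""
    study = RecoveryStudy(n_runs=n_runs)
    for mode_idx, (mode, truth) in enumerate(HET_TRUTHS.items()):
        rec = 0
        cls = 0
        for run in range(n_runs):
            seed = derive_seed(base_seed, 10, mode_idx, run)
            profile = simulate_profile(truth, seed, n_reads=n_reads, rounds=rounds)
            if site_recovered(profile, truth.site):
                rec += 1
            arch = classify_architecture(profile.top_kmer(), truth.half_a, truth.half_b)
            if arch.klass == mode:
                cls += 1
        study.recovery[mode] = 100.0 * rec / n_runs
        study.classification[mode] = 100.0 * cls / n_runs
    return study


def run_genomescape_recovery(
    base_seed: int,
    n_runs: int = 20,
    n_reads: int = 100_000,
    rounds: int = 3,
    n_sites: int = 50,
    genome_len: int = 620_000,
) -> RecoveryStudy:
    """Heterodimer vs parental-homodimer AUC on planted emergent-site peaks.

    Peaks are +/-100 bp around planted emergent sites; negatives are the
    equal-length regions +/-5 kb from each peak center.
    """
    het = HET_TRUTHS["emergent"]
    study = RecoveryStudy(n_runs=n_runs)
    above_0_9 = 0
    above_parents = 0
    for run in range(n_runs):
        seed = derive_seed(base_seed, 20, run)
        het_profile = simulate_profile(het, derive_seed(seed, 0), n_reads=n_reads, rounds=rounds)
        parent_profiles = [
            simulate_profile(p, derive_seed(seed, i + 1), n_reads=n_reads, rounds=rounds)
            for i, p in enumerate(PARENT_TRUTHS)
        ]
        config = SimulationConfig(n_reads=n_reads, rounds=rounds, rng_seed=derive_seed(seed, 9))
        genome = simulate_genome_and_peaks(het, genome_len, n_sites, config)
        peaks = genome.peaks[het.dimer_id]
        negatives, _ = flank_negatives(peaks, genome.chrom_sizes(), offset=5000)
        seq = genome.sequences[genome.chrom]

        def scores(profile: BindingProfile, intervals) -> list[float]:
            return [score_interval(seq[iv.start : iv.end], profile)[0] for iv in intervals]

        het_auc = roc_curve(scores(het_profile, peaks), scores(het_profile, negatives)).auc
        parent_auc = tuple(
            roc_curve(scores(p, peaks), scores(p, negatives)).auc for p in parent_profiles
        )
        study.het_aucs.append(het_auc)
        study.parent_aucs.append(parent_auc)
        above_0_9 += het_auc > 0.9
        above_parents += het_auc > max(parent_auc)
    study.pct_het_auc_above_0_9 = 100.0 * above_0_9 / n_runs
    study.pct_het_auc_above_parents = 100.0 * above_parents / n_runs
    return study


def run_snp_recovery(
    base_seed: int,
    n_runs: int = 20,
    n_reads: int = 100_000,
    rounds: int = 3,
    n_create: int = 20,
    n_destroy: int = 10,
    n_neutral: int = 20,
    noise_factor: float = 0.25,
    threshold: float = 2.0,
) -> RecoveryStudy:
    """Recovery of site-creating variants as >= 2-fold gains at F = 25%."""
    het = HET_TRUTHS["emergent"]
    study = RecoveryStudy(n_runs=n_runs)
    created_total = 0
    created_hit = 0
    neutral_total = 0
    neutral_quiet = 0
    for run in range(n_runs):
        seed = derive_seed(base_seed, 30, run)
        profile = simulate_profile(het, derive_seed(seed, 0), n_reads=n_reads, rounds=rounds)
        config = SimulationConfig(n_reads=n_reads, rounds=rounds, rng_seed=derive_seed(seed, 1))
        genome, snps, labels = simulate_snp_panel(
            None, het, n_create, n_destroy, n_neutral, config
        )
        result = snp_scan(
            snps, [profile], genome.sequences, noise_factor=noise_factor, threshold=threshold
        )
        gains = set(
            result.hits.loc[result.hits["direction"] == "gain", "snp_id"]
        )
        fc = result.fold_changes[profile.dimer_id]
        for _, row in labels.iterrows():
            if row["label"] == "create":
                created_total += 1
                created_hit += row["snp_id"] in gains
            elif row["label"] == "neutral":
                neutral_total += 1
                neutral_quiet += abs(np.log2(fc[row["snp_id"]])) < 1.0
    study.pct_create_snps_gained = 100.0 * created_hit / created_total
    study.pct_neutral_snps_quiet = 100.0 * neutral_quiet / neutral_total
    return study
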