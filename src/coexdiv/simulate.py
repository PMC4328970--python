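"""Synthetic data with known ground truth for every pipeline stage.

Three generators are provided:

* expression datasets for two conditions across developmental stages, with
  planted coexpression modules (shared between conditions or specific to
  one) and negative-binomial tag-count noise around TPM-scaled means;
* pairs of aligned coding sequences differing by exact, verified numbers of
  synonymous and nonsynonymous single-base changes;
* SNP tables with per-individual diploid genotypes in two groups at planted
  allele frequencies.

Module structure is planted through a latent stage trajectory shared by all
genes of a module: on the log-expression scale each module gene follows
``sqrt(rho) * L + sqrt(1-rho) * eps`` with the module trajectory ``L`` and
independent gene noise ``eps`` both standard normal, so any two module
genes correlate at ``rho`` while background genes are uncorrelated.

All randomness flows through explicit integer seeds; identical seed and
configuration give bit-identical output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionDataset
from .selection import BASES, STOP_CODONS, SnpRecord, translate_codon

__all__ = [
    "SyntheticExpressionConfig",
    "PlantedTruth",
    "generate_expression_dataset",
    "generate_coding_alignment",
    "generate_snp_table",
    "BACKGROUND",
]

BACKGROUND = "background"
DEFAULT_CONDITIONS = ("A", "B")
# prenatal stages: days post-coitus; postnatal: days post-natum
DEFAULT_STAGE_NAMES = ("dpc35", "dpc49", "dpc63", "dpc77", "dpc91")


@dataclass
class SyntheticExpressionConfig:
    """Design of a planted two-condition expression experiment.

    ``module_sizes`` lists the planted modules: the first
    ``shared_modules`` entries are planted with identical gene membership
    in both conditions, the remaining ``specific_modules`` entries
    alternate between the two conditions (first extra module in condition
    one, second in condition two, ...).  Genes not in any module of a
    condition are uncorrelated background there.
    """

    n_genes: int = 400
    n_stages: int = 5
    n_replicates_per_stage: int = 2  # the emulated study used one library per stage
    module_sizes: tuple[int, ...] = (60, 60, 60)
    shared_modules: int = 1
    specific_modules: int = 2
    within_module_correlation: float = 0.8
    library_size: int = 3_500_000
    dispersion: float = 300.0  # NB size parameter; larger -> closer to Poisson
    amplitude: float = 1.5  # log2-scale swing of the latent trajectories
    stage_share: float = 0.5  # fraction of latent variance from the stage trajectory
    background_amplitude: float = 0.0  # log2-scale swing of background genes
    baseline_log2_range: tuple[float, float] = (5.0, 10.0)  # reliably quantified TPM range
    # regulated genes sit in the mid-expression range, so the swinging
    # module mass stays a small fraction of the library and does not
    # compositionally distort the stable background
    module_baseline_log2_range: tuple[float, float] = (5.0, 7.5)
    seed: int = 0
    conditions: tuple[str, str] = DEFAULT_CONDITIONS
    period: str = "prenatal"

    def __post_init__(self) -> None:
        if self.shared_modules + self.specific_modules != len(self.module_sizes):
            raise ValueError(
                "module_sizes must list shared_modules + specific_modules entries"
            )
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("sum of module_sizes exceeds n_genes")
        if not 0 < self.within_module_correlation <= 1:
            raise ValueError("within_module_correlation must lie in (0, 1]")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.n_stages < 1 or self.n_replicates_per_stage < 1:
            raise ValueError("need >=1 stage and >=1 replicate per stage")


@dataclass
class PlantedTruth:
    """Ground-truth module membership per condition.

    ``labels`` maps condition -> Series gene -> planted module label
    (``"background"`` for unplanted genes); ``specificity`` maps planted
    module label -> "shared" or the condition it is specific to.
    """

    labels: dict[str, pd.Series]
    specificity: dict[str, str] = field(default_factory=dict)

    def genes_in(self, condition: str, module: str) -> list[str]:
        lab = self.labels[condition]
        return list(lab.index[lab == module])


def _orthogonalize_rows(latents: np.ndarray) -> np.ndarray:
    """Center, mutually orthogonalize (Gram-Schmidt) and re-standardize the
    module latent vectors, so distinct modules of one condition have exactly
    zero sample correlation — the planted between-module structure."""
    out = latents - latents.mean(axis=1, keepdims=True)
    n_samples = out.shape[1]
    for i in range(out.shape[0]):
        for j in range(min(i, n_samples - 1)):
            prev = out[j]
            out[i] = out[i] - (out[i] @ prev) / (prev @ prev) * prev
        sd = out[i].std()
        if sd > 0:
            out[i] = out[i] / sd
    return out


def _stage_names(n_stages: int) -> list[str]:
    if n_stages <= len(DEFAULT_STAGE_NAMES):
        return list(DEFAULT_STAGE_NAMES[:n_stages])
    return [f"stage{i + 1}" for i in range(n_stages)]


def generate_expression_dataset(
    config: SyntheticExpressionConfig,
) -> tuple[dict[str, ExpressionDataset], PlantedTruth]:
    """Simulate tag-count matrices for two conditions with planted modules.

    Returns one :class:`ExpressionDataset` per condition and the planted
    truth.  Counts are negative-binomial around per-gene means obtained by
    scaling relative log-normal expression levels to ``library_size`` tags.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = pd.Index([f"g{i:05d}" for i in range(cfg.n_genes)])
    stages = _stage_names(cfg.n_stages)
    n_samples = cfg.n_stages * cfg.n_replicates_per_stage
    cond1, cond2 = cfg.conditions

    # gene membership blocks (consecutive gene blocks, deterministic layout)
    labels = {c: pd.Series(BACKGROUND, index=genes, dtype=object) for c in cfg.conditions}
    specificity: dict[str, str] = {}
    module_conditions: list[tuple[str, tuple[str, ...]]] = []
    cursor = 0
    spec_cycle = itertools.cycle(cfg.conditions)
    for m, size in enumerate(cfg.module_sizes):
        name = f"M{m + 1}"
        block = genes[cursor : cursor + size]
        cursor += size
        if m < cfg.shared_modules:
            conds = cfg.conditions
            specificity[name] = "shared"
        else:
            conds = (next(spec_cycle),)
            specificity[name] = conds[0]
        module_conditions.append((name, tuple(conds)))
        for c in conds:
            labels[c].loc[block] = name

    truth = PlantedTruth(labels={c: labels[c].copy() for c in cfg.conditions},
                         specificity=specificity)

    # per-gene baseline abundance on the log2 scale, shared across conditions
    lo, hi = cfg.baseline_log2_range
    base = rng.uniform(lo, hi, cfg.n_genes)  # log2 TPM-ish baselines
    planted_any = np.zeros(cfg.n_genes, dtype=bool)
    for c in cfg.conditions:
        planted_any |= (labels[c] != BACKGROUND).to_numpy()
    mlo, mhi = cfg.module_baseline_log2_range
    base[planted_any] = rng.uniform(mlo, mhi, int(planted_any.sum()))
    rho = cfg.within_module_correlation
    # counting noise attenuates the latent correlation on the observed
    # count scale; inflate the latent share so realized within-module
    # Pearson correlation targets rho (log2-scale NB noise variance
    # ~ (1/ln2)^2 / dispersion at high counts)
    noise_var = (1.0 / np.log(2.0)) ** 2 / cfg.dispersion
    attenuation = cfg.amplitude**2 / (cfg.amplitude**2 + noise_var)
    rho_latent = min(rho / attenuation, 1.0)
    a, b = np.sqrt(rho_latent), np.sqrt(1.0 - rho_latent)

    datasets: dict[str, ExpressionDataset] = {}
    for c in cfg.conditions:
        # module latent per sample: a smooth stage trajectory shared by the
        # module plus coherent replicate-level deviation, both module-wide
        w_stage = np.sqrt(cfg.stage_share if cfg.n_replicates_per_stage > 1 else 1.0)
        w_repl = np.sqrt(1.0 - w_stage**2)
        cond_modules = [name for name, conds in module_conditions if c in conds]
        latents = np.empty((len(cond_modules), n_samples))
        for i in range(len(cond_modules)):
            traj = rng.normal(size=cfg.n_stages)  # module trajectory over stages
            repl = rng.normal(size=n_samples)  # coherent replicate deviation
            latents[i] = w_stage * np.repeat(traj, cfg.n_replicates_per_stage) + w_repl * repl
        latents = _orthogonalize_rows(latents)

        z = np.zeros((cfg.n_genes, n_samples))
        for i, name in enumerate(cond_modules):
            members = labels[c] == name
            noise = rng.normal(size=(int(members.sum()), n_samples))
            z[members.to_numpy()] = a * latents[i] + b * noise
        bg = (labels[c] == BACKGROUND).to_numpy()
        # background genes are mutually uncorrelated and (by default) flat
        # across stages: like real non-DE genes they carry only counting
        # noise, so the DEG filter removes them before network construction
        z_bg = rng.normal(size=(int(bg.sum()), n_samples))

        amp = np.full(cfg.n_genes, cfg.amplitude)
        amp[bg] = cfg.background_amplitude
        z[bg] = z_bg
        # lognormal mean correction keeps each gene's expected abundance at
        # its baseline regardless of amplitude
        log2_mean = base[:, None] + amp[:, None] * z - (amp[:, None] ** 2) * np.log(2.0) / 2.0
        # scale to the library against the baseline composition (z = 0), so
        # a module's swing does not compositionally distort the expected
        # counts of unrelated genes; realized totals then fluctuate mildly
        # around library_size like real sequencing depth does
        rel = 2.0 ** log2_mean
        rel /= (2.0 ** base).sum()
        mean_counts = rel * cfg.library_size
        # NB(size=k, mean=m): p = k / (k + m)
        k = cfg.dispersion
        p = k / (k + mean_counts)
        counts = rng.negative_binomial(k, p)

        sample_ids = [
            f"{c}_{stage}_r{r + 1}"
            for stage in stages
            for r in range(cfg.n_replicates_per_stage)
        ]
        samples = pd.DataFrame(
            {
                "condition": c,
                "stage": np.repeat(stages, cfg.n_replicates_per_stage),
                "period": cfg.period,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        counts_df = pd.DataFrame(counts, index=genes, columns=sample_ids)
        datasets[c] = ExpressionDataset(counts_df, samples)
    return datasets, truth


# ---------------------------------------------------------------------------
# Coding-sequence generators
# ---------------------------------------------------------------------------

def _random_codon(rng: np.random.Generator) -> str:
    while True:
        codon = "".join(rng.choice(list(BASES), 3))
        if codon not in STOP_CODONS:
            return codon


def _single_base_changes(codon: str):
    """All (position, base, mutant_codon) single-base variants of a codon."""
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            yield pos, base, codon[:pos] + base + codon[pos + 1:]


def generate_coding_alignment(
    codon_length: int, n_nonsyn: int, n_syn: int, seed: int
) -> tuple[str, str, int, int]:
    """Generate a reference CDS and a derived CDS differing by exactly
    ``n_nonsyn`` nonsynonymous and ``n_syn`` synonymous single-base changes
    (at most one change per codon; no stop codons anywhere).

    Returns ``(reference, derived, n_nonsyn, n_syn)``; the substitution
    counts are re-verified against the genetic code before returning.
    """
    if codon_length < n_nonsyn + n_syn:
        raise ValueError("codon_length must be >= n_nonsyn + n_syn")
    if n_nonsyn < 0 or n_syn < 0:
        raise ValueError("change counts must be nonnegative")
    rng = np.random.default_rng(seed)

    ref_codons: list[str] = []
    derived_codons: list[str] = []
    # choose codon slots for each change class
    slots = rng.permutation(codon_length)
    nonsyn_slots = set(slots[:n_nonsyn].tolist())
    syn_slots = set(slots[n_nonsyn : n_nonsyn + n_syn].tolist())

    for i in range(codon_length):
        want = "nonsyn" if i in nonsyn_slots else "syn" if i in syn_slots else None
        while True:
            codon = _random_codon(rng)
            if want is None:
                ref_codons.append(codon)
                derived_codons.append(codon)
                break
            aa = translate_codon(codon)
            choices = [
                m
                for _, _, m in _single_base_changes(codon)
                if m not in STOP_CODONS
                and ((translate_codon(m) == aa) == (want == "syn"))
            ]
            if choices:
                ref_codons.append(codon)
                derived_codons.append(choices[rng.integers(len(choices))])
                break
            # codon admits no change of the wanted class (e.g. no synonymous
            # change from ATG); draw another codon

    reference = "".join(ref_codons)
    derived = "".join(derived_codons)
    # verify against the genetic code
    got_nonsyn = sum(
        translate_codon(reference[i : i + 3]) != translate_codon(derived[i : i + 3])
        for i in range(0, len(reference), 3)
    )
    got_diff = sum(x != y for x, y in zip(reference, derived))
    assert got_nonsyn == n_nonsyn and got_diff == n_nonsyn + n_syn
    return reference, derived, n_nonsyn, n_syn


def generate_snp_table(
    references: dict[str, str],
    n_individuals_per_group: int,
    allele_frequency_spectrum: tuple[float, float] = (0.3, 0.3),
    seed: int = 0,
    snps_per_kb: float = 5.0,
    groups: tuple[str, str] = ("domestic", "wild"),
) -> tuple[list[SnpRecord], pd.DataFrame]:
    """Plant SNPs on reference coding sequences with per-group allele
    frequencies drawn from a Beta(``a``, ``b``) spectrum.

    Each individual is diploid; genotypes at a site are binomial in the
    group's planted frequency.  Returns the SNP records and a truth table
    (gene, position, ref, alt, planted frequency per group).
    """
    if n_individuals_per_group < 1:
        raise ValueError("need >=1 individual per group")
    if not references:
        raise ValueError("empty reference set")
    rng = np.random.default_rng(seed)
    a_par, b_par = allele_frequency_spectrum
    records: list[SnpRecord] = []
    truth_rows = []
    for gene in sorted(references):
        seq = references[gene].upper()
        n_sites = max(1, round(len(seq) * snps_per_kb / 1000))
        positions = sorted(
            rng.choice(len(seq), size=min(n_sites, len(seq)), replace=False).tolist()
        )
        for pos0 in positions:
            ref_base = seq[pos0]
            codon_start = (pos0 // 3) * 3
            within = pos0 - codon_start
            codon = seq[codon_start : codon_start + 3]
            # alt alleles creating an in-frame stop codon are never planted
            candidates = [
                b
                for b in BASES
                if b != ref_base
                and (len(codon) < 3
                     or codon[:within] + b + codon[within + 1:] not in STOP_CODONS)
            ]
            if not candidates:
                continue
            alt_base = rng.choice(candidates)
            freqs = {g: float(rng.beta(a_par, b_par)) for g in groups}
            genotypes: dict[str, list[tuple[int, int] | None]] = {}
            for g in groups:
                draws = rng.binomial(1, freqs[g], size=(n_individuals_per_group, 2))
                genotypes[g] = [tuple(int(x) for x in d) for d in draws]
            records.append(SnpRecord(gene, pos0 + 1, ref_base, str(alt_base), genotypes))
            truth_rows.append(
                {"gene": gene, "position": pos0 + 1, "ref": ref_base, "alt": alt_base,
                 **{f"freq_{g}": freqs[g] for g in groups}}
            )
    return records, pd.DataFrame(truth_rows)
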