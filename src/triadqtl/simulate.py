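"""Synthetic three-generation F2 intercross with a recorded planted truth.

The generator emulates the statistical structure of a divergent-breed F2
resource population: two founder lines with strongly diverged allele
frequencies, an F1 generation, and a large F2 generation produced in
batches from recorded matings. Meioses place crossovers by a Poisson
process on the genetic map (Haldane, no interference), so F2 chromosomes
are mosaics of founder-line haplotypes and carry the long-range linkage
disequilibrium typical of such crosses.

On top of the genotypes, expression is generated per transcript as a
latent log-scale value composed of planted cis/trans dosage effects,
block-correlated module factors, sex, batch, and Gaussian noise, then
exponentiated and normalised to tags-per-million. Traits combine
expression-mediated effects, direct QTL effects, a polygenic deviate drawn
against the realised genomic kinship, sex, batch, and noise. Every planted
effect is recorded in a :class:`PlantedTruth` ledger so that recovery can
be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, ExpressionMatrix, TraitTable
from . import phenotypes
from .mixedmodel import compute_grm


class SimConfigError(ValueError):
    """Raised for an invalid simulation configuration."""


@dataclass
class CisEffect:
    """A planted cis-eQTL: the SNP sits inside the transcript's gene."""

    transcript: str
    snp: str
    var_share: float


@dataclass
class TransEffect:
    """A planted trans-eQTL: SNP and transcript on unrelated loci."""

    transcript: str
    snp: str
    var_share: float


@dataclass
class ModuleSpec:
    """A co-expression module: ``size`` transcripts sharing a latent factor
    that contributes ``factor_share`` of each member's log-expression
    variance."""

    size: int
    factor_share: float


@dataclass
class TraitSpec:
    """One simulated trait and its variance decomposition.

    ``mediators`` maps transcript IDs to the share of trait variance
    explained through that transcript's (standardised log) expression.
    ``direct_qtl`` optionally plants a QTL acting on the trait without an
    expression intermediate. Shares must sum to < 1; the remainder is
    i.i.d. Gaussian noise.
    """

    name: str
    mediators: list = field(default_factory=list)  # [(transcript, share), ...]
    direct_qtl: tuple | None = None  # (snp, share)
    h2: float = 0.0
    sex_share: float = 0.0
    batch_share: float = 0.0

    def total_share(self) -> float:
        s = sum(w for _, w in self.mediators) + self.h2 + self.sex_share + self.batch_share
        if self.direct_qtl is not None:
            s += self.direct_qtl[1]
        return s


@dataclass
class SimConfig:
    """Parameters of the synthetic cross. Defaults give a desk-scale
    population with the study design's shape: ~500 F2s in 6 batches, two
    sexes, divergent founder lines."""

    seed: int = 0
    n_f2: int = 500
    n_chrom: int = 5
    chrom_length_bp: int = 100_000_000
    n_snps_per_chrom: int = 1_000
    recomb_rate_cm_per_mb: float = 1.0
    fixed_diff_fraction: float = 0.3
    n_transcripts: int = 2_000
    planted_cis: list = field(default_factory=list)
    planted_trans: list = field(default_factory=list)
    module_spec: list = field(default_factory=list)
    trait_spec: list = field(default_factory=list)
    n_batches: int = 6
    n_founder_sires: int = 2
    n_founder_dams: int = 17
    n_f1_boars: int = 9
    n_f1_sows: int = 59
    expr_sex_share: float = 0.02
    expr_batch_share: float = 0.05
    expr_log_sd: float = 0.5
    geno_missing_rate: float = 0.0
    expr_missing_rate: float = 0.0
    trait_missing_rate: float = 0.0
    gp_ph_target_r: float = -0.39

    def __post_init__(self) -> None:
        self.planted_cis = [e if isinstance(e, CisEffect) else CisEffect(*e) for e in self.planted_cis]
        self.planted_trans = [e if isinstance(e, TransEffect) else TransEffect(*e) for e in self.planted_trans]
        self.module_spec = [m if isinstance(m, ModuleSpec) else ModuleSpec(*m) for m in self.module_spec]
        self.trait_spec = [t if isinstance(t, TraitSpec) else TraitSpec(**t) if isinstance(t, dict) else t for t in self.trait_spec]
        self.validate()

    def validate(self) -> None:
        if self.n_chrom < 1 or self.n_snps_per_chrom < 1:
            raise SimConfigError("need at least one chromosome and one SNP per chromosome")
        if self.n_f2 < 1:
            raise SimConfigError("n_f2 must be positive")
        if not 0.0 <= self.fixed_diff_fraction <= 1.0:
            raise SimConfigError("fixed_diff_fraction must lie in [0, 1]")
        for eff in list(self.planted_cis) + list(self.planted_trans):
            if not 0.0 <= eff.var_share < 1.0:
                raise SimConfigError(f"variance share {eff.var_share} outside [0, 1)")
        for mod in self.module_spec:
            if not 0.0 <= mod.factor_share < 1.0:
                raise SimConfigError("module factor share outside [0, 1)")
        for ts in self.trait_spec:
            if not 0.0 <= ts.h2 < 1.0:
                raise SimConfigError(f"trait {ts.name}: h2 {ts.h2} outside [0, 1)")
            if ts.total_share() >= 1.0:
                raise SimConfigError(f"trait {ts.name}: variance shares sum to >= 1")
        # per-transcript share budget
        shares: dict[str, float] = {}
        for eff in list(self.planted_cis) + list(self.planted_trans):
            shares[eff.transcript] = shares.get(eff.transcript, 0.0) + eff.var_share
        mod_genes = sum(m.size for m in self.module_spec)
        if mod_genes > self.n_transcripts:
            raise SimConfigError("module sizes exceed n_transcripts")
        base = self.expr_sex_share + self.expr_batch_share
        for tx, s in shares.items():
            if s + base >= 1.0:
                raise SimConfigError(f"transcript {tx}: variance shares sum to >= 1")

    # -- ID helpers -------------------------------------------------------
    def snp_ids(self) -> list:
        return [f"snp_c{c + 1}_{i:04d}" for c in range(self.n_chrom) for i in range(self.n_snps_per_chrom)]

    def transcript_ids(self) -> list:
        return [f"tx{i:05d}" for i in range(1, self.n_transcripts + 1)]


@dataclass
class PlantedTruth:
    """Ledger of every planted effect, recoverable record by record."""

    cis_eqtls: list = field(default_factory=list)
    trans_eqtls: list = field(default_factory=list)
    module_labels: dict = field(default_factory=dict)
    trait_specs: list = field(default_factory=list)
    variance_decomposition: dict = field(default_factory=dict)
    module_factors: dict = field(default_factory=dict)  # module -> per-F2-sample factor

    def to_dict(self) -> dict:
        return {
            "cis_eqtls": [asdict(e) for e in self.cis_eqtls],
            "trans_eqtls": [asdict(e) for e in self.trans_eqtls],
            "module_labels": dict(self.module_labels),
            "trait_specs": [
                {
                    "name": t.name,
                    "mediators": [list(m) for m in t.mediators],
                    "direct_qtl": list(t.direct_qtl) if t.direct_qtl else None,
                    "h2": t.h2,
                    "sex_share": t.sex_share,
                    "batch_share": t.batch_share,
                }
                for t in self.trait_specs
            ],
            "variance_decomposition": self.variance_decomposition,
            "module_factors": {str(k): list(map(float, v)) for k, v in self.module_factors.items()},
        }


# ---------------------------------------------------------------------------
# genotype simulation
# ---------------------------------------------------------------------------

def _meiosis(parent_haps: np.ndarray, chrom_slices, cm_pos: np.ndarray, rng) -> np.ndarray:
    """One gamete from a diploid parent.

    ``parent_haps`` is (2, n_snps) over all chromosomes; crossovers are laid
    down per chromosome by a Poisson process on the genetic map (Haldane).
    """
    gamete = np.empty(parent_haps.shape[1], dtype=parent_haps.dtype)
    for sl in chrom_slices:
        pos = cm_pos[sl]
        length_m = (pos[-1] - pos[0]) / 100.0
        n_x = rng.poisson(length_m)
        start = rng.integers(2)
        if n_x == 0:
            gamete[sl] = parent_haps[start, sl]
            continue
        xo = np.sort(rng.uniform(pos[0], pos[-1], size=n_x))
        phase = (start + np.searchsorted(xo, pos, side="right")) % 2
        gamete[sl] = parent_haps[phase, np.arange(sl.start, sl.stop)]
    return gamete


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Simulate founder, F1 and F2 genotypes through a recorded pedigree.

    Founder haplotypes are drawn per breed: a ``fixed_diff_fraction`` of
    SNPs is fixed for alternate alleles in the two lines (alt frequency 1
    in line A, 0 in line B); the remainder get independent Beta(0.5, 0.5)
    frequencies per line, yielding both fully and partially informative
    markers. Returns dosages for all generations; analyses typically use
    ``f2_samples()``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_snps = config.n_chrom * config.n_snps_per_chrom

    # marker map: evenly spaced positions per chromosome
    snp_ids = config.snp_ids()
    chroms = np.repeat(np.arange(1, config.n_chrom + 1), config.n_snps_per_chrom)
    within = np.tile(np.arange(config.n_snps_per_chrom), config.n_chrom)
    spacing = config.chrom_length_bp / config.n_snps_per_chrom
    pos = ((within + 0.5) * spacing).astype(np.int64) + 1
    snp_map = pd.DataFrame({"snp": snp_ids, "chrom": chroms, "pos": np.tile(pos[: config.n_snps_per_chrom], config.n_chrom)})
    chrom_slices = [
        slice(c * config.n_snps_per_chrom, (c + 1) * config.n_snps_per_chrom)
        for c in range(config.n_chrom)
    ]
    cm_pos = snp_map["pos"].to_numpy() * config.recomb_rate_cm_per_mb / 1e6

    # breed allele frequencies
    n_fixed = int(round(config.fixed_diff_fraction * n_snps))
    fixed_idx = rng.choice(n_snps, size=n_fixed, replace=False)
    freq_a = rng.beta(0.5, 0.5, size=n_snps)
    freq_b = rng.beta(0.5, 0.5, size=n_snps)
    freq_a[fixed_idx] = 1.0
    freq_b[fixed_idx] = 0.0

    sires = [f"WD_S{i + 1}" for i in range(config.n_founder_sires)]
    dams = [f"EH_D{i + 1}" for i in range(config.n_founder_dams)]
    f1_boars = [f"F1_B{i + 1:02d}" for i in range(config.n_f1_boars)]
    f1_sows = [f"F1_S{i + 1:02d}" for i in range(config.n_f1_sows)]
    f2 = [f"F2_{i + 1:04d}" for i in range(config.n_f2)]

    haps: dict[str, np.ndarray] = {}
    for s in sires:
        haps[s] = (rng.random((2, n_snps)) < freq_a).astype(np.int8)
    for d in dams:
        haps[d] = (rng.random((2, n_snps)) < freq_b).astype(np.int8)

    ped_rows = []
    for s in sires:
        ped_rows.append((s, "0", "0", 1, 0))
    for d in dams:
        ped_rows.append((d, "0", "0", 2, 0))

    def _mate(sire: str, dam: str) -> np.ndarray:
        return np.stack(
            [
                _meiosis(haps[sire], chrom_slices, cm_pos, rng),
                _meiosis(haps[dam], chrom_slices, cm_pos, rng),
            ]
        )

    f1_parents: dict[str, tuple] = {}
    for i, b in enumerate(f1_boars):
        sire = sires[i % len(sires)]
        dam = dams[i % len(dams)]
        haps[b] = _mate(sire, dam)
        f1_parents[b] = (sire, dam)
        ped_rows.append((b, sire, dam, 1, 1))
    for i, s in enumerate(f1_sows):
        sire = sires[(i + 1) % len(sires)]
        dam = dams[(i + len(f1_boars)) % len(dams)]
        haps[s] = _mate(sire, dam)
        f1_parents[s] = (sire, dam)
        ped_rows.append((s, sire, dam, 2, 1))

    # F2 matings: each sow mated to one boar; litters fill n_f2 evenly.
    sow_boar = {s: f1_boars[i % len(f1_boars)] for i, s in enumerate(f1_sows)}
    sow_cycle = [f1_sows[i % len(f1_sows)] for i in range(config.n_f2)]
    sow_cycle.sort()  # group litters together
    f2_sex = rng.integers(1, 3, size=config.n_f2)
    batch_of_sow = {s: (i % config.n_batches) + 1 for i, s in enumerate(f1_sows)}

    f2_dosage = np.empty((config.n_f2, n_snps), dtype=np.float64)
    f2_batch = np.empty(config.n_f2, dtype=np.int64)
    for i, name in enumerate(f2):
        sow = sow_cycle[i]
        boar = sow_boar[sow]
        child = _mate(boar, sow)
        f2_dosage[i] = child.sum(axis=0)
        f2_batch[i] = batch_of_sow[sow]
        ped_rows.append((name, boar, sow, int(f2_sex[i]), 2))

    all_samples = sires + dams + f1_boars + f1_sows + f2
    dosage = np.vstack(
        [haps[s].sum(axis=0) for s in sires + dams + f1_boars + f1_sows]
        + [f2_dosage]
    ).astype(np.float64)

    if config.geno_missing_rate > 0:
        mask = rng.random(dosage.shape) < config.geno_missing_rate
        dosage[mask] = np.nan

    ped = pd.DataFrame(ped_rows, columns=["sample", "sire", "dam", "sex", "generation"]).set_index("sample")
    sex = ped["sex"].copy()
    batch = pd.Series(0, index=pd.Index(all_samples, name="sample"), dtype=int)
    batch.loc[f2] = f2_batch

    return GenotypeMatrix(
        dosages=pd.DataFrame(dosage, index=pd.Index(all_samples, name="sample"), columns=snp_ids),
        snp_map=snp_map,
        pedigree=ped[["sire", "dam", "generation"]],
        sex=sex,
        batch=batch,
    )


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------

def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v, dtype=float)
    return (v - v.mean()) / sd


def simulate_expression(genotypes: GenotypeMatrix, config: SimConfig):
    """Generate a TPM matrix for the F2 samples plus the truth ledger.

    Per transcript the latent log-expression is a weighted sum of
    standardised components (cis/trans dosage, module factor, sex, batch)
    with weights ``sqrt(share)`` and Gaussian noise carrying the remaining
    share, so each planted share equals the component's realised fraction
    of latent variance up to sampling error. Latents are exponentiated and
    each sample's column is rescaled to one million tags.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    f2 = genotypes.f2_samples()
    n = len(f2)
    tx_ids = config.transcript_ids()
    m = len(tx_ids)

    dos = genotypes.dosages.loc[f2]
    for eff in list(config.planted_cis) + list(config.planted_trans):
        if eff.snp not in genotypes.snps:
            raise SimConfigError(f"planted SNP {eff.snp} absent from genotypes")
        if eff.transcript not in tx_ids:
            raise SimConfigError(f"planted transcript {eff.transcript} unknown")
        if eff.var_share > 0 and np.nanstd(dos[eff.snp].to_numpy()) == 0:
            raise SimConfigError(
                f"planted SNP {eff.snp} is monomorphic among the F2 samples; "
                "plant effects at informative markers (see informative_snps)"
            )
    sex = genotypes.sex.reindex(f2).to_numpy().astype(float)
    batch = genotypes.batch.reindex(f2).to_numpy()

    sex_comp = _standardize(sex)
    batch_levels = np.unique(batch)
    batch_idx = np.searchsorted(batch_levels, batch)

    # module membership: consecutive blocks from the start of the ID list
    module_labels = dict.fromkeys(tx_ids, 0)
    factors = {}
    cursor = 0
    for k, mod in enumerate(config.module_spec, start=1):
        for tx in tx_ids[cursor : cursor + mod.size]:
            module_labels[tx] = k
        factors[k] = _standardize(rng.normal(size=n))
        cursor += mod.size

    cis_by_tx: dict[str, list] = {}
    for eff in config.planted_cis:
        cis_by_tx.setdefault(eff.transcript, []).append(eff)
    trans_by_tx: dict[str, list] = {}
    for eff in config.planted_trans:
        trans_by_tx.setdefault(eff.transcript, []).append(eff)

    latent = np.empty((n, m))
    decomposition = {}
    for j, tx in enumerate(tx_ids):
        shares = {"sex": config.expr_sex_share, "batch": config.expr_batch_share}
        # per-transcript sex direction and batch level effects: a shift
        # common to all transcripts would be a library-size effect that
        # TPM normalisation removes exactly
        sex_sign = 1.0 if rng.random() < 0.5 else -1.0
        batch_comp = _standardize(rng.normal(size=batch_levels.size)[batch_idx])
        z = np.sqrt(config.expr_sex_share) * sex_sign * sex_comp + np.sqrt(config.expr_batch_share) * batch_comp
        for eff in cis_by_tx.get(tx, []):
            g = _standardize(np.nan_to_num(dos[eff.snp].to_numpy(), nan=np.nanmean(dos[eff.snp].to_numpy())))
            z = z + np.sqrt(eff.var_share) * g
            shares[f"cis:{eff.snp}"] = eff.var_share
        for eff in trans_by_tx.get(tx, []):
            g = _standardize(np.nan_to_num(dos[eff.snp].to_numpy(), nan=np.nanmean(dos[eff.snp].to_numpy())))
            z = z + np.sqrt(eff.var_share) * g
            shares[f"trans:{eff.snp}"] = eff.var_share
        lab = module_labels[tx]
        if lab:
            share = config.module_spec[lab - 1].factor_share
            z = z + np.sqrt(share) * factors[lab]
            shares[f"module:{lab}"] = share
        total = sum(shares.values())
        z = z + np.sqrt(1.0 - total) * rng.normal(size=n)
        shares["noise"] = 1.0 - total
        latent[:, j] = z
        if total > 0:
            decomposition[tx] = shares

    base_log = rng.normal(np.log(50.0), 1.2, size=m)
    raw = np.exp(base_log[None, :] + config.expr_log_sd * latent)
    tpm = raw / raw.sum(axis=1, keepdims=True) * 1e6
    if config.expr_missing_rate > 0:
        mask = rng.random(tpm.shape) < config.expr_missing_rate
        tpm[mask] = np.nan

    annotation = _annotate_transcripts(tx_ids, cis_by_tx, genotypes, config, rng)
    expr = ExpressionMatrix(
        values=pd.DataFrame(tpm, index=f2, columns=tx_ids),
        annotation=annotation,
    )
    truth = PlantedTruth(
        cis_eqtls=list(config.planted_cis),
        trans_eqtls=list(config.planted_trans),
        module_labels=module_labels,
        trait_specs=list(config.trait_spec),
        variance_decomposition=decomposition,
        module_factors={k: v.copy() for k, v in factors.items()},
    )
    return expr, truth


def _annotate_transcripts(tx_ids, cis_by_tx, genotypes, config, rng) -> pd.DataFrame:
    """Place each transcript on the genome; cis targets straddle their SNP."""
    snp_map = genotypes.snp_map
    rows = []
    gene_len = 10_000
    for i, tx in enumerate(tx_ids):
        if tx in cis_by_tx:
            snp = cis_by_tx[tx][0].snp
            chrom = int(snp_map.loc[snp, "chrom"])
            center = int(snp_map.loc[snp, "pos"])
        else:
            chrom = int(rng.integers(1, config.n_chrom + 1))
            center = int(rng.integers(gene_len, config.chrom_length_bp - gene_len))
        start = max(1, center - gene_len // 2)
        end = start + gene_len
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((tx, f"GENE_{tx}", chrom, start, end, strand))
    return pd.DataFrame(rows, columns=["transcript", "gene", "chrom", "start", "end", "strand"])


# ---------------------------------------------------------------------------
# trait simulation
# ---------------------------------------------------------------------------

def simulate_traits(expr: ExpressionMatrix, genotypes: GenotypeMatrix, config: SimConfig) -> TraitTable:
    """Simulate the configured traits plus the glycolytic-potential block.

    Each configured trait mixes standardised components weighted by
    ``sqrt(share)``: mediator log-expression, direct-QTL dosage, a
    polygenic deviate drawn from N(0, K) with K the realised genomic
    kinship of the F2s, sex, batch, and i.i.d. noise. Additionally, the
    muscle-chemistry block (glucose, glycogen, glucose-6-phosphate,
    lactate) is simulated around published-scale means, glycolytic
    potential is derived from it via :mod:`triadqtl.phenotypes`, and pH at
    24 h is generated as a decreasing function of GP plus noise.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    samples = expr.samples
    n = len(samples)
    log_expr = expr.log_values()

    sex = genotypes.sex.reindex(samples).to_numpy().astype(float)
    batch = genotypes.batch.reindex(samples).to_numpy()
    sex_comp = _standardize(sex)
    batch_levels = np.unique(batch)

    poly_chol = None
    if any(ts.h2 > 0 for ts in config.trait_spec):
        K = compute_grm(genotypes.subset(samples=samples)).values
        w, U = np.linalg.eigh(K)
        poly_chol = U * np.sqrt(np.clip(w, 0.0, None))

    data = {}
    for ts in config.trait_spec:
        for tx, _ in ts.mediators:
            if tx not in log_expr.columns:
                raise SimConfigError(f"trait {ts.name}: mediator {tx} not in expression matrix")
        if ts.direct_qtl is not None and ts.direct_qtl[0] not in genotypes.snps:
            raise SimConfigError(f"trait {ts.name}: direct QTL SNP {ts.direct_qtl[0]} unknown")
        y = np.zeros(n)
        for tx, share in ts.mediators:
            y = y + np.sqrt(share) * _standardize(log_expr[tx].to_numpy())
        if ts.direct_qtl is not None:
            snp, share = ts.direct_qtl
            g = genotypes.dosages.loc[samples, snp].to_numpy()
            g = np.nan_to_num(g, nan=np.nanmean(g))
            y = y + np.sqrt(share) * _standardize(g)
        if ts.h2 > 0:
            y = y + np.sqrt(ts.h2) * _standardize(poly_chol @ rng.normal(size=n))
        if ts.sex_share > 0:
            y = y + np.sqrt(ts.sex_share) * sex_comp
        if ts.batch_share > 0:
            be = rng.normal(size=batch_levels.size)
            y = y + np.sqrt(ts.batch_share) * _standardize(be[np.searchsorted(batch_levels, batch)])
        y = y + np.sqrt(1.0 - ts.total_share()) * rng.normal(size=n)
        data[ts.name] = y

    # glycolytic-potential block (concentrations in umol/g, non-negative)
    glucose = np.clip(rng.normal(8.0, 5.0, size=n), 0.05, None)
    glycogen = np.clip(rng.normal(16.0, 10.0, size=n), 0.05, None)
    g6p = np.clip(rng.normal(0.16, 0.3, size=n), 0.0, None)
    lactate = np.clip(rng.normal(88.4, 21.7, size=n), 1.0, None)
    gp = phenotypes.derive_gp(glucose, glycogen, g6p, lactate)
    rho = abs(config.gp_ph_target_r)
    ph24 = 5.67 + 0.17 * (
        np.sign(config.gp_ph_target_r) * rho * _standardize(np.asarray(gp))
        + np.sqrt(1.0 - rho**2) * rng.normal(size=n)
    )
    data.update(
        glucose=glucose,
        glycogen=glycogen,
        g6p=g6p,
        lactate=lactate,
        RG=phenotypes.derive_rg(glucose, glycogen),
        GP=gp,
        pH24h=ph24,
    )

    table = pd.DataFrame(data, index=samples)
    if config.trait_missing_rate > 0:
        mask = rng.random(table.shape) < config.trait_missing_rate
        table = table.mask(mask)
    return TraitTable(values=table)


def informative_snps(genotypes: GenotypeMatrix, min_maf: float = 0.3) -> pd.Index:
    """SNPs whose realised F2 minor-allele frequency is at least ``min_maf``.

    Effects should be planted at informative markers: a SNP whose founder
    lines happen to share an allele can be (nearly) monomorphic in the F2
    and carries no mappable signal. Breed-fixed SNPs segregate at MAF 0.5
    and always qualify.
    """
    dos = genotypes.dosages.loc[genotypes.f2_samples()]
    p = np.nanmean(dos.to_numpy(), axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    return genotypes.snps[maf >= min_maf]


def simulate_dataset(config: SimConfig):
    """Run all three generators; returns (genotypes, expression, traits, truth)."""
    genotypes = simulate_genotypes(config)
    expr, truth = simulate_expression(genotypes, config)
    traits = simulate_traits(expr, genotypes, config)
    return genotypes, expr, traits, truth
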