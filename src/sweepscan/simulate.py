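"""Synthetic two-population SNP-array data with drift, LD, sweeps and truth.

The generator emulates a medium-density (~50K) array genotyped in two breeds
that diverged by pure drift, plus optional planted signals:

1. ancestral allele frequencies are drawn uniformly within ``maf_bounds``
   (randomly polarised so either allele can be minor);
2. each population's frequencies evolve independently for
   ``divergence_generations`` of Wright-Fisher binomial resampling with
   2 * ``pop_size`` chromosomes — this sets the drift-level background
   differentiation (defaults target a genome-wide mean Fst of about 0.03);
3. at each planted sweep the selected allele's frequency in the target
   population follows the deterministic logistic trajectory
   p' = p (1+s) / (1 + s p) for the whole divergence time, and flanking SNPs
   within reach are pulled toward a sweep-coupled allele with weight
   exp(-distance / decay_bp), scaled by the sweep's progress (a phenomenological
   hitch-hiking proxy, not a recombination-explicit model);
4. haplotypes are emitted by a first-order Markov walk along each chromosome
   with target adjacent-SNP allelic correlation ``rho`` and the population's
   marginal frequencies (transition probabilities are clamped so marginals are
   preserved exactly); two haplotypes per individual are summed to dosages;
5. inside LD-divergent regions the Markov coupling sign is inverted in the
   target population without touching marginals, creating signal for the
   regional-LD detector that is invisible to Fst;
6. missing calls are planted iid at ``missing_rate``.

Identical configs (including the seed) give byte-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset, SNP_COLUMNS

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class Sweep:
    """A planted selective sweep (positive selection in one population)."""

    chromosome: int
    position_bp: int
    s: float = 0.1                 # selection coefficient per generation
    decay_bp: int = 500_000        # hitch-hiking pull length scale
    target_population: int = 0     # index into population_labels

    def __post_init__(self):
        if self.s <= 0:
            raise ValueError("selection coefficient s must be > 0")


@dataclass(frozen=True)
class LdDivergentRegion:
    """A span where haplotype coupling is sign-inverted in one population."""

    chromosome: int
    start_bp: int
    end_bp: int
    target_population: int = 0


@dataclass
class SimConfig:
    """Study-condition defaults: a 29-autosome ~52K array, two breeds of
    364 and 410 animals, adjacent-SNP correlation ~0.3, and drift calibrated
    to a background mean Fst of ~0.0285 (57 generations at Ne = 500)."""

    seed: int
    n_chromosomes: int = 29
    snps_per_chromosome: int = 1800
    chromosome_length_bp: int = 100_000_000
    n_samples: tuple[int, int] = (364, 410)
    population_labels: tuple[str, str] = ("pop1", "pop2")
    maf_bounds: tuple[float, float] = (0.05, 0.5)
    rho: float = 0.3
    divergence_generations: int = 57
    pop_size: int = 500
    sweeps: list[Sweep] = field(default_factory=list)
    ld_divergent: list[LdDivergentRegion] = field(default_factory=list)
    ld_mode: str = "decouple"  # "decouple" (rho -> 0) or "invert" (rho -> -rho)
    missing_rate: float = 0.005

    def __post_init__(self):
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.ld_mode not in ("decouple", "invert"):
            raise ValueError("ld_mode must be 'decouple' or 'invert'")
        for sw in self.sweeps:
            if not 1 <= sw.chromosome <= self.n_chromosomes:
                raise ValueError(f"sweep chromosome {sw.chromosome} out of range")
            if not 0 <= sw.position_bp <= self.chromosome_length_bp:
                raise ValueError(f"sweep position {sw.position_bp} outside chromosome")


@dataclass
class SyntheticTruth:
    """Ground truth of the planted signals plus the echoed generator config."""

    sweeps: pd.DataFrame          # chromosome, position_bp, snp_id, s, freqs...
    ld_regions: pd.DataFrame      # chromosome, start_bp, end_bp, target
    config: SimConfig
    target_frequencies: pd.DataFrame | None = None  # per-SNP emitted marginals


def logistic_trajectory(p0: float, s: float, generations: int) -> float:
    """Deterministic selection trajectory p' = p(1+s) / (1 + s p)."""
    p = float(p0)
    for _ in range(generations):
        p = p * (1.0 + s) / (1.0 + s * p)
    return p


def simulate_dataset(config: SimConfig) -> tuple[GenotypeDataset, SyntheticTruth]:
    """Generate a :class:`GenotypeDataset` plus its :class:`SyntheticTruth`."""
    rng = np.random.default_rng(config.seed)
    n_chr = config.n_chromosomes
    m = config.snps_per_chromosome
    total = n_chr * m

    # -- map: near-regular spacing with jitter, unique increasing positions --
    spacing = config.chromosome_length_bp / (m + 1)
    chrom_col = np.repeat(np.arange(1, n_chr + 1), m)
    pos_col = np.empty(total, dtype=np.int64)
    for c in range(n_chr):
        base = spacing * (1 + np.arange(m))
        jitter = rng.uniform(-0.4 * spacing, 0.4 * spacing, m)
        pos = np.sort(np.round(base + jitter).astype(np.int64))
        pos = np.maximum.accumulate(pos + np.arange(m) * 0)  # sorted already
        for i in range(1, m):                                # enforce uniqueness
            if pos[i] <= pos[i - 1]:
                pos[i] = pos[i - 1] + 1
        pos_col[c * m : (c + 1) * m] = pos

    base_idx = rng.integers(0, 4, total)
    other = (base_idx + rng.integers(1, 4, total)) % 4
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{c}_{i % m + 1}" for c, i in zip(chrom_col, range(total))],
            "chromosome": chrom_col,
            "position_bp": pos_col,
            "allele_a": _BASES[base_idx],
            "allele_b": _BASES[other],
        }
    )[list(SNP_COLUMNS)]

    # -- ancestral frequencies and per-population drift ----------------------
    lo, hi = config.maf_bounds
    p0 = rng.uniform(lo, hi, total)
    flip = rng.random(total) < 0.5
    p0 = np.where(flip, 1.0 - p0, p0)

    n2 = 2 * config.pop_size
    freqs = []
    for _ in range(2):
        p = p0.copy()
        for _ in range(config.divergence_generations):
            p = rng.binomial(n2, p) / n2
        freqs.append(p)

    # -- planted sweeps -------------------------------------------------------
    sweep_rows = []
    for sw in config.sweeps:
        sel = np.flatnonzero(chrom_col == sw.chromosome)
        j = sel[np.argmin(np.abs(pos_col[sel] - sw.position_bp))]
        p_anc = p0[j]
        p_swept = logistic_trajectory(p_anc, sw.s, config.divergence_generations)
        progress = (p_swept - p_anc) / max(1.0 - p_anc, 1e-12)
        tgt = freqs[sw.target_population]
        tgt[j] = p_swept
        # hitch-hiking proxy: pull flanking loci toward a coupled allele
        dist = np.abs(pos_col[sel] - pos_col[j]).astype(float)
        w = np.exp(-dist / sw.decay_bp) * progress
        coupled = (rng.random(len(sel)) < tgt[sel]).astype(float)
        tgt[sel] = tgt[sel] + w * (coupled - tgt[sel])
        tgt[j] = p_swept
        other_pop = freqs[1 - sw.target_population]
        sweep_rows.append(
            (sw.chromosome, int(pos_col[j]), snps["snp_id"].iloc[j],
             sw.s, sw.decay_bp, sw.target_population,
             float(p_anc), float(p_swept), float(abs(tgt[j] - other_pop[j])))
        )
    truth_sweeps = pd.DataFrame(
        sweep_rows,
        columns=["chromosome", "position_bp", "snp_id", "s", "decay_bp",
                 "target_population", "p_ancestral", "p_swept", "freq_difference"],
    )

    # -- haplotype emission ---------------------------------------------------
    labels = list(config.population_labels)
    dosage_blocks = []
    for pidx, (n_ind, f) in enumerate(zip(config.n_samples, freqs)):
        inverted = np.zeros(total, dtype=bool)  # transitions with flipped coupling
        for reg in config.ld_divergent:
            if reg.target_population != pidx:
                continue
            inverted |= (
                (chrom_col == reg.chromosome)
                & (pos_col >= reg.start_bp)
                & (pos_col <= reg.end_bp)
            )
        hap = _emit_haplotypes(
            rng, f, chrom_col, inverted, config.rho, 2 * n_ind, config.ld_mode
        )
        dosage_blocks.append((hap[0::2] + hap[1::2]).astype(np.int8))
    dosages = np.vstack(dosage_blocks)

    if config.missing_rate > 0:
        miss = rng.random(dosages.shape) < config.missing_rate
        dosages[miss] = MISSING

    samples = [
        f"{labels[p]}_{i + 1}"
        for p, n_ind in enumerate(config.n_samples)
        for i in range(n_ind)
    ]
    population_of = {s: s.rsplit("_", 1)[0] for s in samples}
    ds = GenotypeDataset(snps, samples, population_of, dosages)
    ds.validate()

    truth_ld = pd.DataFrame(
        [(r.chromosome, r.start_bp, r.end_bp, r.target_population)
         for r in config.ld_divergent],
        columns=["chromosome", "start_bp", "end_bp", "target_population"],
    )
    target_freqs = snps[["snp_id", "chromosome", "position_bp"]].copy()
    target_freqs["f_pop1"] = freqs[0]
    target_freqs["f_pop2"] = freqs[1]
    return ds, SyntheticTruth(truth_sweeps, truth_ld, config, target_freqs)


def _emit_haplotypes(
    rng: np.random.Generator,
    f: np.ndarray,
    chrom_col: np.ndarray,
    inverted: np.ndarray,
    rho: float,
    n_hap: int,
    ld_mode: str = "decouple",
) -> np.ndarray:
    """First-order Markov walk along each chromosome with marginals ``f``.

    Transition probabilities are clamped so the marginal frequency at every
    SNP is preserved exactly; the effective correlation of a transition is
    attenuated only where the marginals make ``rho`` unattainable.  For
    transitions whose *both* endpoints lie in an LD-divergent region the
    coupling is set to 0 (``decouple``, the default: a correlation change the
    eigenvalue comparison can see along the whole region) or to ``-rho``
    (``invert``; note a uniform sign flip is a diag(+/-1) similarity of the
    window correlation matrix, so it leaves the eigenvalues of fully interior
    windows unchanged and is only visible at region boundaries).
    """
    total = len(f)
    out = np.empty((n_hap, total), dtype=np.int8)
    sigma = np.sqrt(np.clip(f * (1.0 - f), 0.0, None))
    new_chrom = np.ones(total, dtype=bool)
    new_chrom[1:] = chrom_col[1:] != chrom_col[:-1]

    prev = np.zeros(n_hap, dtype=np.int8)
    for j in range(total):
        fj = f[j]
        if new_chrom[j]:
            x = (rng.random(n_hap) < fj).astype(np.int8)
        else:
            fi, si, sj = f[j - 1], sigma[j - 1], sigma[j]
            if inverted[j] and inverted[j - 1]:
                r = 0.0 if ld_mode == "decouple" else -rho
            else:
                r = rho
            if si == 0.0 or sj == 0.0 or fi in (0.0, 1.0):
                x = (rng.random(n_hap) < fj).astype(np.int8)
            else:
                cov = r * si * sj
                if cov >= 0:
                    cov = min(cov, (1.0 - fj) * fi, fj * (1.0 - fi))
                else:
                    cov = max(cov, -fj * fi, -(1.0 - fj) * (1.0 - fi))
                p11 = fj + cov / fi
                p01 = fj - cov / (1.0 - fi)
                p = np.where(prev == 1, p11, p01)
                x = (rng.random(n_hap) < p).astype(np.int8)
        out[:, j] = x
        prev = x
    return out


# ---------------------------------------------------------------------------
# Scenario factories and detection metrics
# ---------------------------------------------------------------------------

def null_config(seed: int, **overrides) -> SimConfig:
    """Two populations drawn from the same pool (no divergence, no signals)."""
    overrides.setdefault("divergence_generations", 0)
    return SimConfig(seed=seed, **overrides)


def sweep_scenario(
    seed: int,
    n_chromosomes: int = 5,
    snps_per_chromosome: int = 2000,
    s: float = 0.1,
    divergence_generations: int = 100,
    decay_bp: int = 500_000,
    with_ld_regions: bool = False,
    **overrides,
) -> SimConfig:
    """One planted sweep per chromosome at a seed-determined position.

    With ``with_ld_regions`` every chromosome additionally carries one
    2 Mb LD-divergent (coupling-swap) region well away from its sweep.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2**20]))
    length = overrides.get("chromosome_length_bp", 100_000_000)
    sweeps, regions = [], []
    for c in range(1, n_chromosomes + 1):
        pos = int(rng.uniform(0.15, 0.45) * length)
        sweeps.append(Sweep(chromosome=c, position_bp=pos, s=s, decay_bp=decay_bp,
                            target_population=int(rng.integers(0, 2))))
        if with_ld_regions:
            start = int(rng.uniform(0.6, 0.8) * length)
            regions.append(
                LdDivergentRegion(chromosome=c, start_bp=start,
                                  end_bp=start + 2_000_000,
                                  target_population=int(rng.integers(0, 2)))
            )
    return SimConfig(
        seed=seed,
        n_chromosomes=n_chromosomes,
        snps_per_chromosome=snps_per_chromosome,
        divergence_generations=divergence_generations,
        sweeps=sweeps,
        ld_divergent=regions,
        **overrides,
    )


def evaluate_detection(
    detections: pd.DataFrame,
    truth_loci: pd.DataFrame,
    tolerance_bp: int = 500_000,
) -> dict:
    """Power / false-discovery proportion / localisation error of a detector.

    ``detections`` needs columns ``chromosome`` and a bp column (``summit_bp``,
    ``central_bp`` or ``position_bp``); ``truth_loci`` needs ``chromosome`` and
    ``position_bp`` (or start/end span, matched by distance to the span).
    """
    bp_col = next(
        (c for c in ("summit_bp", "central_bp", "position_bp")
         if c in detections.columns), None,
    )
    if bp_col is None:
        raise ValueError("detections need a summit_bp/central_bp/position_bp column")
    det = detections[["chromosome", bp_col]].to_numpy()

    if "position_bp" in truth_loci.columns:
        spans = truth_loci[["chromosome", "position_bp", "position_bp"]].to_numpy()
    else:
        spans = truth_loci[["chromosome", "start_bp", "end_bp"]].to_numpy()

    def dist(d, t):
        if d[0] != t[0]:
            return np.inf
        if t[1] <= d[1] <= t[2]:
            return 0.0
        return min(abs(d[1] - t[1]), abs(d[1] - t[2]))

    n_truth = len(spans)
    hits = np.full(n_truth, np.inf)
    det_true = np.zeros(len(det), dtype=bool)
    for i, d in enumerate(det):
        for t_i, t in enumerate(spans):
            dd = dist(d, t)
            if dd <= tolerance_bp:
                det_true[i] = True
                hits[t_i] = min(hits[t_i], dd)

    power = float((hits <= tolerance_bp).sum() / n_truth) if n_truth else np.nan
    fdp = float((~det_true).sum() / len(det)) if len(det) else 0.0
    found = hits[np.isfinite(hits)]
    return {
        "power": power,
        "fdp": fdp,
        "n_detections": int(len(det)),
        "n_truth": int(n_truth),
        "localization_bp": float(found.mean()) if len(found) else np.nan,
    }


def truth_to_frame(truth: SyntheticTruth) -> pd.DataFrame:
    """Flatten the truth tables for TSV export."""
    sw = truth.sweeps.assign(kind="sweep")
    ld = truth.ld_regions.assign(kind="ld_divergent")
    return pd.concat([sw, ld], ignore_index=True)


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    return d
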