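"""Seeded generator for every input the pipeline consumes, with planted truth.

Each generator plants a known ground truth (motif positions and strands,
occupancy classes, summit offsets, footprint boundaries, allelic biases,
supercoiling dip, domain-border placement) and emits it alongside the
simulated data, so every downstream analysis can be asserted against truth
without external datasets.

Default parameters mirror the spatial statistics the analyses are designed
to detect: oriented summit offsets of -15 bp (TOP2B) and +12 bp (RAD21)
around the CTCF motif, exo footprints at +13..+26 (forward strand) and
-27..-13 (reverse strand), an occupancy split of roughly 50% triple /
49% CTCF+RAD21 / 1% CTCF+TOP2B, an allele-frequency correlation of 0.4 at
coverage 20, and a supercoiling dip of depth -0.5 and width 300 bp.

Motif strands are balanced exactly: sites come in +/- pairs that share
their drawn occupancy class and oriented offsets, so the planted
*un-oriented* offset distribution is mirror-symmetric by construction and
its population median is exactly zero — symmetry is part of the planted
truth, not a sampling outcome.

Every function is deterministic given the config seed: each generator
draws from its own seed stream, so outputs do not depend on call order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, special, stats

from .allelic import AllelicCount
from .intervals import GenomicInterval, Peak, Read
from .motifs import BASES, MotifMatrix, OrientedSite, reverse_complement
from .orientation import Domain
from .profiles import ProbeIntensity

# seed-stream tags (kept < 2**31; combined with the user seed)
_STREAM_GENOME = 11
_STREAM_PEAKS = 13
_STREAM_EXO = 17
_STREAM_ALLELIC = 19
_STREAM_PROBES = 23
_STREAM_DOMAINS = 29


def write_dataset(config: "SimulationConfig", outdir) -> dict[str, str]:
    """Generate every simulated input and write it under ``outdir``.

    Emits the genome FASTA, the planted motif truth BED, per-factor
    narrowPeak files, the peak truth table, exo reads as tagAlign, the
    allelic count table, the probe table and the domain/site BEDs.
    Deterministic: identical config (including seed) gives byte-identical
    files.  Returns a name -> path mapping.
    """
    import json
    from pathlib import Path

    import pandas as pd

    from . import io as tio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    sequences, sites = simulate_genome_and_motifs(config)
    paths["genome"] = str(out / "genome.fa")
    tio.write_fasta(sequences, paths["genome"])
    paths["motif_truth"] = str(out / "motif_sites.bed")
    tio.write_bed(
        [
            # 1-bp interval at the center, strand = orientation
            GenomicInterval(s.chrom, s.center, s.center + 1, s.orientation)
            for s in sites
        ],
        paths["motif_truth"],
        names=[f"site{i}" for i in range(len(sites))],
    )

    peaks, truth = simulate_peaks(config, sites)
    for factor, plist in peaks.items():
        paths[f"peaks_{factor}"] = str(out / f"{factor}.narrowPeak")
        tio.write_narrowpeak(plist, paths[f"peaks_{factor}"])
    paths["peak_truth"] = str(out / "peak_truth.tsv")
    pd.DataFrame(truth).to_csv(paths["peak_truth"], sep="\t", index=False)

    reads = simulate_exo_reads(config, sites)
    paths["exo"] = str(out / "exo.tagAlign")
    tio.write_tagalign(reads, paths["exo"])

    counts_a, counts_b = simulate_allelic_counts(config)
    paths["allelic"] = str(out / "allelic_counts.tsv")
    from .allelic import write_counts_table

    write_counts_table(counts_a + counts_b, paths["allelic"])

    probes = simulate_probes(config, sites)
    paths["probes"] = str(out / "probes.tsv")
    from .profiles import write_probe_table

    write_probe_table(probes, paths["probes"])

    domains, placed = simulate_domains(config, sites)
    paths["domains"] = str(out / "domains.bed")
    with open(paths["domains"], "w") as fh:
        for d in domains:
            iv = d.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    paths["placed_sites"] = str(out / "domain_sites.bed")
    tio.write_bed(
        [
            GenomicInterval(s.chrom, s.center, s.center + 1, s.orientation)
            for s in placed
        ],
        paths["placed_sites"],
    )
    paths["manifest"] = str(out / "manifest.json")
    with open(paths["manifest"], "w") as fh:
        json.dump(
            {"seed": config.seed, "n_sites": config.n_sites,
             "files": sorted(Path(p).name for p in paths.values())},
            fh,
            indent=2,
            sort_keys=True,
        )
    return paths


def default_ctcf_matrix() -> MotifMatrix:
    """A 14-column count matrix with a G-rich CTCF-like consensus.

    Column counts put ~96% of mass on the consensus base (~22 bits total
    information), so instances sampled from the matrix rarely carry more
    than the 2-3 mismatches a p <= 1e-4 scan still accepts — planted
    instances are recoverable essentially by construction.
    """
    consensus = "CCACCAGGTGGCAG"
    counts = np.full((len(consensus), 4), 1.0)
    for j, base in enumerate(consensus):
        counts[j, BASES.index(base)] = 97.0
    return MotifMatrix(counts, pseudocount=1.0, name="CTCF_core")


@dataclass
class ExoModel:
    footprint_forward: tuple[int, int] = (13, 26)  # inclusive oriented offsets
    footprint_reverse: tuple[int, int] = (-27, -13)
    reads_per_site: int = 50
    noise_rate: float = 0.2
    read_length: int = 36
    flank: int = 50


@dataclass
class AllelicModel:
    n_sites: int = 5000
    coverage: int = 20
    correlation: float = 0.4  # target Pearson r of allele frequencies
    latent_sd: float = 1.2  # total SD of the per-site logit bias


@dataclass
class SupercoilModel:
    dip_depth: float = -0.5
    dip_sigma: float = 300.0  # bp
    probe_spacing: int = 200
    noise_sd: float = 0.25


@dataclass
class DomainModel:
    n_domains: int = 50
    border_fraction: float = 0.5  # fraction of sites re-placed near borders
    border_zone: float = 0.1  # "near" = within this fraction of domain size


@dataclass
class SimulationConfig:
    seed: int = 0
    genome: Mapping[str, int] = field(default_factory=lambda: {"chrS": 3_200_000})
    n_sites: int = 2000
    site_spacing: int = 1500  # minimum distance between planted motif centers
    motif: MotifMatrix = field(default_factory=default_ctcf_matrix)
    occupancy_proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "CTCF+RAD21+TOP2B": 0.50,
            "CTCF+RAD21": 0.49,
            "CTCF+TOP2B": 0.01,
        }
    )
    offset_model: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "TOP2B": (-15.0, 5.0),
            "CTCF": (0.0, 5.0),
            "RAD21": (12.0, 5.0),
        }
    )
    peak_width: tuple[int, int] = (200, 400)
    exo: ExoModel = field(default_factory=ExoModel)
    allelic: AllelicModel = field(default_factory=AllelicModel)
    supercoil: SupercoilModel = field(default_factory=SupercoilModel)
    domains: DomainModel = field(default_factory=DomainModel)

    def __post_init__(self) -> None:
        total = sum(self.occupancy_proportions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("occupancy proportions must sum to 1")
        if any(sd < 0 for _, sd in self.offset_model.values()):
            raise ValueError("offset standard deviations must be non-negative")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed % (2**31), stream])


def plant_sites(config: SimulationConfig) -> list[OrientedSite]:
    """Plant oriented motif centers, evenly spaced with jitter.

    Strands strictly alternate (+, -, +, -, ...) so they are balanced
    exactly and consecutive sites form mirror pairs.
    """
    rng = config.rng(_STREAM_GENOME)
    lengths = dict(config.genome)
    total = sum(lengths.values())
    sites: list[OrientedSite] = []
    remaining = config.n_sites
    chroms = list(lengths)
    for ci, chrom in enumerate(chroms):
        n = (
            remaining
            if ci == len(chroms) - 1
            else int(round(config.n_sites * lengths[chrom] / total))
        )
        n = min(n, remaining)
        remaining -= n
        if n == 0:
            continue
        usable = lengths[chrom] - 2 * config.site_spacing
        if usable < n * config.site_spacing:
            raise ValueError(
                f"{chrom}: cannot place {n} sites {config.site_spacing} bp apart"
            )
        base = np.linspace(
            config.site_spacing, lengths[chrom] - config.site_spacing, n
        ).astype(int)
        jitter = rng.integers(
            -config.site_spacing // 4, config.site_spacing // 4 + 1, size=n
        )
        centers = base + jitter
        for i, c in enumerate(centers):
            sites.append(OrientedSite(chrom, int(c), "+" if i % 2 == 0 else "-"))
    return sites


def plant_uniform_features(config: SimulationConfig) -> list[OrientedSite]:
    """Plant oriented features at uniform i.i.d. positions (no min spacing).

    Used for the supercoiling study: genomic features such as TSSs or CTCF
    sites are irregularly spaced, and uniform placement reproduces the
    same probe-to-feature distance statistics as the uniformly re-drawn
    random background — the observed/background comparison then differs
    only through the planted dip, not through feature spacing.
    """
    rng = config.rng(_STREAM_GENOME)
    feats: list[OrientedSite] = []
    lengths = dict(config.genome)
    total = sum(lengths.values())
    remaining = config.n_sites
    chroms = list(lengths)
    for ci, chrom in enumerate(chroms):
        n = (
            remaining
            if ci == len(chroms) - 1
            else int(round(config.n_sites * lengths[chrom] / total))
        )
        n = min(n, remaining)
        remaining -= n
        pos = rng.integers(0, lengths[chrom], size=n)
        ori = rng.choice(["+", "-"], size=n)
        feats.extend(OrientedSite(chrom, int(p), str(o)) for p, o in zip(pos, ori))
    return feats


def simulate_genome_and_motifs(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[OrientedSite]]:
    """Random background sequence with motif instances planted at sites.

    Background bases are i.i.d. uniform; each instance is sampled
    column-wise from the motif matrix and embedded (reverse-complemented
    for minus-oriented sites) so that its center matches the planted
    center under the scanner's center convention.
    """
    rng = config.rng(_STREAM_GENOME)
    sites = plant_sites(config)
    probs = config.motif.probabilities()
    w = config.motif.width
    sequences: dict[str, str] = {}
    arrays = {
        chrom: rng.integers(0, 4, size=length).astype(np.int8)
        for chrom, length in config.genome.items()
    }
    for site in sites:
        inst = np.array(
            [rng.choice(4, p=probs[j]) for j in range(w)], dtype=np.int8
        )
        if site.orientation == "+":
            start = site.center - w // 2
        else:
            start = site.center - (math.ceil(w / 2) - 1)
            inst = 3 - inst[::-1]  # reverse complement
        arrays[site.chrom][start : start + w] = inst
    for chrom, arr in arrays.items():
        sequences[chrom] = "".join(BASES[b] for b in arr)
    return sequences, sites


def simulate_peaks(
    config: SimulationConfig, sites: Sequence[OrientedSite]
) -> tuple[dict[str, list[Peak]], list[dict]]:
    """ChIP-seq peaks per factor around planted sites.

    Each +/- site pair shares one drawn occupancy class and one set of
    oriented offsets (mirror-symmetry of the planted geometry); each member
    factor gets a peak whose summit sits at the orientation-corrected
    offset from the motif center, with width Uniform(200, 400) and a
    lognormal signal boosted ~2x at triple sites.  Returns the peaks and a
    per-site truth table (class, oriented offset per factor).
    """
    rng = config.rng(_STREAM_PEAKS)
    classes = list(config.occupancy_proportions)
    probs = np.array([config.occupancy_proportions[c] for c in classes])
    factors = sorted({f for c in classes for f in c.split("+")})
    peaks: dict[str, list[Peak]] = {f: [] for f in factors}
    truth: list[dict] = []
    wmin, wmax = config.peak_width

    n = len(sites)
    for pair_start in range(0, n, 2):
        cls = classes[rng.choice(len(classes), p=probs)]
        members = cls.split("+")
        offsets = {
            f: int(round(rng.normal(mu, sd)))
            for f, (mu, sd) in config.offset_model.items()
        }
        for idx in (pair_start, pair_start + 1):
            if idx >= n:
                break
            site = sites[idx]
            sign = 1 if site.orientation == "+" else -1
            row = {"site_id": idx, "occupancy_class": cls, "orientation": site.orientation}
            for f in members:
                d = offsets.get(f, 0)
                summit = site.center + sign * d
                width = int(rng.integers(wmin, wmax + 1))
                margin = min(60, width // 4)
                left = int(rng.integers(margin, width - margin))
                start = summit - left
                is_triple = len(members) == 3
                signal = float(
                    rng.lognormal(mean=(1.0 if is_triple else 0.3), sigma=0.5)
                )
                peaks[f].append(
                    Peak(
                        GenomicInterval(site.chrom, start, start + width),
                        summit=summit,
                        signal=signal,
                        factor=f,
                        name=f"{f}_site{idx}",
                    )
                )
                row[f"offset_{f}"] = d
            truth.append(row)
    return peaks, truth


def simulate_exo_reads(
    config: SimulationConfig, sites: Sequence[OrientedSite]
) -> list[Read]:
    """Strand-specific exonuclease-stop reads with planted footprints.

    Per site, each read is noise with probability ``noise_rate`` (5' end
    uniform in the +/-flank window, either strand) and signal otherwise:
    forward-strand 5' ends uniform over the planted forward footprint
    offsets, reverse-strand over the reverse footprint.  Oriented offsets
    and strands are mapped back through the site orientation, so the
    planted truth is stated once in motif coordinates.
    """
    rng = config.rng(_STREAM_EXO)
    exo = config.exo
    fwd_lo, fwd_hi = exo.footprint_forward
    rev_lo, rev_hi = exo.footprint_reverse
    reads: list[Read] = []
    for site in sites:
        for _ in range(exo.reads_per_site):
            if rng.random() < exo.noise_rate:
                offset = int(rng.integers(-exo.flank, exo.flank + 1))
                oriented_strand = "+" if rng.random() < 0.5 else "-"
            else:
                oriented_strand = "+" if rng.random() < 0.5 else "-"
                if oriented_strand == "+":
                    offset = int(rng.integers(fwd_lo, fwd_hi + 1))
                else:
                    offset = int(rng.integers(rev_lo, rev_hi + 1))
            if site.orientation == "+":
                pos = site.center + offset
                strand = oriented_strand
            else:
                pos = site.center - offset
                strand = "-" if oriented_strand == "+" else "+"
            if strand == "+":
                iv = GenomicInterval(site.chrom, pos, pos + exo.read_length, "+")
            else:
                iv = GenomicInterval(
                    site.chrom, pos - exo.read_length + 1, pos + 1, "-"
                )
            reads.append(Read(iv))
    return reads


def _predicted_frequency_correlation(
    latent_rho: float, latent_sd: float, coverage: int, n_nodes: int = 40
) -> float:
    """Pearson correlation of binomial allele frequencies implied by a
    bivariate-normal logit bias, by Gauss-Hermite quadrature (no sampling)."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    w1 = weights / weights.sum()
    f = special.expit(latent_sd * nodes)
    mean_f = float(w1 @ f)
    var_f = float(w1 @ (f - mean_f) ** 2)
    samp = float(w1 @ (f * (1 - f))) / coverage
    # E[f(X) f(Y)] for correlated standard normals via conditional quadrature
    rho = np.clip(latent_rho, -0.999, 0.999)
    cond = rho * nodes[:, None] + math.sqrt(1 - rho**2) * nodes[None, :]
    fy = special.expit(latent_sd * cond)
    e_ff = float(w1 @ (f * (fy @ w1)))
    cov = e_ff - mean_f**2
    return cov / (var_f + samp)


def solve_latent_correlation(
    target: float, latent_sd: float, coverage: int
) -> float:
    """Latent logit correlation that induces the target frequency
    correlation after logistic squashing and binomial sampling noise."""
    if target == 0:
        return 0.0
    hi = _predicted_frequency_correlation(0.999, latent_sd, coverage)
    if abs(target) >= abs(hi):
        raise ValueError(
            f"target correlation {target} not attainable at coverage {coverage}"
        )
    return float(
        optimize.brentq(
            lambda r: _predicted_frequency_correlation(r, latent_sd, coverage)
            - target,
            -0.999,
            0.999,
        )
    )


def simulate_allelic_counts(
    config: SimulationConfig, factors: tuple[str, str] = ("CTCF", "TOP2B")
) -> tuple[list[AllelicCount], list[AllelicCount]]:
    """F1-cross allelic read counts for two factors at shared sites.

    Each site carries a latent logit bias per factor, bivariate normal
    with the correlation solved so that the induced Pearson correlation of
    the binomial allele frequencies matches the configured target.  With
    target 0 the factors are independent and (with zero latent SD) every
    site is unbiased.
    """
    rng = config.rng(_STREAM_ALLELIC)
    model = config.allelic
    rho = solve_latent_correlation(model.correlation, model.latent_sd, model.coverage)
    z = rng.standard_normal((model.n_sites, 2))
    xb = rho * z[:, 0] + math.sqrt(1 - rho**2) * z[:, 1]
    pi_a = special.expit(model.latent_sd * z[:, 0])
    pi_b = special.expit(model.latent_sd * xb)
    counts_a, counts_b = [], []
    for i in range(model.n_sites):
        ka = int(rng.binomial(model.coverage, pi_a[i]))
        kb = int(rng.binomial(model.coverage, pi_b[i]))
        counts_a.append(AllelicCount(i, factors[0], ka, model.coverage - ka))
        counts_b.append(AllelicCount(i, factors[1], kb, model.coverage - kb))
    return counts_a, counts_b


def simulate_null_allelic_counts(
    config: SimulationConfig, factors: tuple[str, str] = ("CTCF", "TOP2B")
) -> tuple[list[AllelicCount], list[AllelicCount]]:
    """Unbiased counts: every site has allele probability exactly 0.5."""
    rng = config.rng(_STREAM_ALLELIC)
    n, cov = config.allelic.n_sites, config.allelic.coverage
    ka = rng.binomial(cov, 0.5, size=n)
    kb = rng.binomial(cov, 0.5, size=n)
    return (
        [AllelicCount(i, factors[0], int(k), cov - int(k)) for i, k in enumerate(ka)],
        [AllelicCount(i, factors[1], int(k), cov - int(k)) for i, k in enumerate(kb)],
    )


def simulate_probes(
    config: SimulationConfig, sites: Sequence[OrientedSite]
) -> list[ProbeIntensity]:
    """Microarray probes on a jittered grid with a planted dip at sites.

    Probe value = Gaussian dip of the configured depth/width centered on
    the nearest planted site, plus independent normal noise.  Dip depth 0
    gives pure noise (the null for calibration).
    """
    rng = config.rng(_STREAM_PROBES)
    model = config.supercoil
    centers_by_chrom: dict[str, np.ndarray] = {}
    for s in sites:
        centers_by_chrom.setdefault(s.chrom, []).append(s.center)  # type: ignore[attr-defined]
    centers_by_chrom = {c: np.sort(np.array(v)) for c, v in centers_by_chrom.items()}
    probes: list[ProbeIntensity] = []
    for chrom, length in config.genome.items():
        grid = np.arange(0, length - model.probe_spacing, model.probe_spacing)
        pos = grid + rng.integers(0, model.probe_spacing, size=grid.size)
        noise = rng.normal(0, model.noise_sd, size=pos.size)
        centers = centers_by_chrom.get(chrom)
        for p, eps in zip(pos, noise):
            value = float(eps)
            if centers is not None and centers.size and model.dip_depth != 0:
                j = int(np.searchsorted(centers, p))
                d = min(
                    abs(int(p) - int(centers[k]))
                    for k in (j - 1, j)
                    if 0 <= k < centers.size
                )
                value += model.dip_depth * math.exp(
                    -(d**2) / (2 * model.dip_sigma**2)
                )
            probes.append(ProbeIntensity(chrom, int(p), value))
    return probes


def simulate_domains(
    config: SimulationConfig, sites: Sequence[OrientedSite]
) -> tuple[list[Domain], list[OrientedSite]]:
    """Tile the genome into domains and enrich sites at domain borders.

    Domain boundaries are sorted uniform draws per chromosome.  A
    configured fraction of sites is re-placed uniformly within the border
    zone (outer ``border_zone`` fraction on either end) of a random
    domain; the rest are re-placed uniformly inside a random domain.
    Returns the domains and the re-placed sites (orientation preserved).
    """
    rng = config.rng(_STREAM_DOMAINS)
    model = config.domains
    domains: list[Domain] = []
    for chrom, length in config.genome.items():
        cuts = np.sort(rng.integers(1, length, size=model.n_domains - 1))
        bounds = np.concatenate([[0], cuts, [length]])
        for s, e in zip(bounds[:-1], bounds[1:]):
            if e > s:
                domains.append(Domain(GenomicInterval(chrom, int(s), int(e))))
    placed: list[OrientedSite] = []
    by_chrom: dict[str, list[Domain]] = {}
    for d in domains:
        by_chrom.setdefault(d.interval.chrom, []).append(d)
    for site in sites:
        doms = by_chrom[site.chrom]
        d = doms[int(rng.integers(len(doms)))]
        size = len(d.interval)
        zone = max(1, int(size * model.border_zone))
        if rng.random() < model.border_fraction:
            # uniform over the two border zones
            u = int(rng.integers(2 * zone))
            pos = d.interval.start + u if u < zone else d.interval.end - (u - zone) - 1
        else:
            pos = d.interval.start + int(rng.integers(size))
        placed.append(OrientedSite(site.chrom, int(pos), site.orientation))
    return domains, placed
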