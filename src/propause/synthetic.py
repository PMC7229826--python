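"""Ground-truthed synthetic paused-transcription experiments.

The generator emulates the statistical structure of a spike-in-normalized
PRO-seq experiment contrasting an HDAC-inhibitor treatment against a solvent
control in two biological replicates:

* Each gene ``g`` carries an initiation rate ``I_g`` and a pause-release
  probability ``r_g``.  At steady state, paused-polymerase occupancy at the
  promoter is proportional to ``I_g / r_g`` while the elongating-polymerase
  flux through the gene body is proportional to ``I_g * r_g / (r_g + t)``
  with a termination weight ``t``: raising the release rate moves signal
  from the pause window into the body, which is the treatment effect the
  analysis must detect.
* A configurable subset of "target" genes is drawn from a low-release
  (highly paused) component; under treatment their release probability is
  multiplied by ``f >= 1`` (capped at 1).
* Window counts are negative-binomial with variance ``mu + alpha*mu^2``;
  read 3' ends are then placed uniformly: paused reads at +20..+60 (the
  pause site sits ~20-60 bp downstream of the TSS), elongating reads over
  +70..L-100 so that early-gene-body density responds to release.
* Each sample has a multiplicative depth distortion ``lambda_j`` applied to
  every read count, and a constant-abundance spike-in: spike reads are
  Poisson with mean ``S * lambda_j`` -- independent of condition, but
  carried along by sequencing depth exactly like the primary reads, which
  is what makes spike-in totals informative about cross-sample scale.

Everything is reproducible from a single master seed; per-sample streams
are spawned deterministically.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .formats_io import EndCountTrack, GeneModel, Interval, write_table

logger = logging.getLogger("propause")

CONTROL, TREATED = "control", "treated"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic PRO-seq experiment.

    Defaults describe a desk-scale two-condition, two-replicate design with
    10% highly paused target genes whose pause release triples under
    treatment.
    """

    n_genes: int = 500
    n_targets: int = 50
    replicates: int = 2
    #: gene length ~ lognormal(meanlog, sdlog), redrawn below ``min_gene_length``
    gene_length_meanlog: float = 8.0     # median ~3 kb
    gene_length_sdlog: float = 0.4
    min_gene_length: int = 700
    #: initiation rate I_g ~ lognormal
    initiation_meanlog: float = 0.0
    initiation_sdlog: float = 0.5
    #: release probability r_g ~ Beta(a, b); targets from the low-release component
    release_a: float = 2.0
    release_b: float = 8.0
    target_release_a: float = 2.0
    target_release_b: float = 38.0
    #: multiplier f applied to r_g of targets under treatment (capped at 1)
    treatment_release_multiplier: float = 3.0
    #: termination weight t in body flux r/(r+t)
    termination_weight: float = 0.5
    #: NB dispersion alpha; variance = mu + alpha*mu^2 (0 -> Poisson)
    nb_dispersion: float = 0.05
    reads_per_sample: int = 200_000
    #: fraction of control-library reads allocated to the pause site
    promoter_read_share: float = 0.4
    #: per-sample depth distortion lambda_j; None -> drawn lognormal(0, 0.25)
    depth_distortion: tuple[float, ...] | None = None
    depth_distortion_sdlog: float = 0.25
    spike_reads_base: int = 20_000
    spike_chrom: str = "spike_chr1"
    spike_chrom_length: int = 100_000
    chrom: str = "chr2L"
    intergenic_gap: int = 1_000
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.n_targets <= self.n_genes:
            raise ValueError("need 0 <= n_targets <= n_genes")
        if self.treatment_release_multiplier < 1:
            raise ValueError("treatment_release_multiplier must be >= 1")
        if self.termination_weight < 0 or self.nb_dispersion < 0:
            raise ValueError("rates must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return [f"{c}_rep{r + 1}" for c in (CONTROL, TREATED)
                for r in range(self.replicates)]

    @property
    def conditions(self) -> list[str]:
        return [CONTROL] * self.replicates + [TREATED] * self.replicates


@dataclass
class SimulatedExperiment:
    """In-memory result of :func:`simulate_experiment`."""

    config: SimConfig
    annotation: pd.DataFrame
    genes: dict[str, GeneModel]
    tracks: dict[str, EndCountTrack]
    samples: pd.DataFrame          # sample, condition, replicate, lambda, totals
    truth: pd.DataFrame            # per-gene ground truth
    paths: dict[str, str] = field(default_factory=dict)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean mu, var mu + alpha*mu^2) via gamma-Poisson mixture."""
    mean = np.asarray(mean, dtype=float)
    if alpha == 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mean)
    return rng.poisson(lam)


def _draw_lambdas(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    n = 2 * cfg.replicates
    if cfg.depth_distortion is not None:
        lam = np.asarray(cfg.depth_distortion, dtype=float)
        if lam.shape != (n,) or (lam <= 0).any():
            raise ValueError(f"depth_distortion must be {n} positive values")
        return lam
    return rng.lognormal(0.0, cfg.depth_distortion_sdlog, size=n)


# ---------------------------------------------------------------------------
# PRO-seq experiment
# ---------------------------------------------------------------------------

def simulate_experiment(config: SimConfig, outdir: str | None = None) -> SimulatedExperiment:
    """Simulate a full spike-in PRO-seq experiment.

    Returns in-memory annotation, per-sample :class:`EndCountTrack` objects,
    a sample table and per-gene ground truth; when ``outdir`` is given, also
    writes the exact on-disk formats the pipeline reads (annotation TSV, one
    BED6 read file per sample, ground-truth and sample TSVs).
    """
    cfg = config
    master = np.random.default_rng(np.random.SeedSequence(cfg.seed))

    # --- genes -------------------------------------------------------------
    lengths = np.zeros(cfg.n_genes, dtype=np.int64)
    need = np.ones(cfg.n_genes, dtype=bool)
    floor = max(cfg.min_gene_length, 700)
    n_redrawn = 0
    while need.any():
        draw = master.lognormal(cfg.gene_length_meanlog, cfg.gene_length_sdlog,
                                size=int(need.sum())).astype(np.int64)
        lengths[need] = draw
        need = lengths < floor
        n_redrawn += int(need.sum())
    if n_redrawn:
        logger.info("redrew %d gene lengths below %d bp", n_redrawn, floor)

    strands = np.where(master.random(cfg.n_genes) < 0.5, "+", "-")
    starts = np.zeros(cfg.n_genes, dtype=np.int64)
    cursor = cfg.intergenic_gap
    for i in range(cfg.n_genes):
        starts[i] = cursor
        cursor += lengths[i] + cfg.intergenic_gap
    ends = starts + lengths

    gene_ids = np.array([f"gene{i:05d}" for i in range(cfg.n_genes)])
    is_target = np.zeros(cfg.n_genes, dtype=bool)
    is_target[master.choice(cfg.n_genes, size=cfg.n_targets, replace=False)] = True

    initiation = master.lognormal(cfg.initiation_meanlog, cfg.initiation_sdlog,
                                  size=cfg.n_genes)
    release = np.where(
        is_target,
        master.beta(cfg.target_release_a, cfg.target_release_b, size=cfg.n_genes),
        master.beta(cfg.release_a, cfg.release_b, size=cfg.n_genes))
    release = np.clip(release, 1e-3, 1.0)
    f = cfg.treatment_release_multiplier
    release_treated = np.where(is_target, np.minimum(1.0, f * release), release)

    lambdas = _draw_lambdas(cfg, master)

    t = cfg.termination_weight

    def occupancy(r):
        """(pause weight, body weight) given release probabilities r."""
        return initiation / r, initiation * lengths * r / (r + t)

    wp_c, wb_c = occupancy(release)
    wp_t, wb_t = occupancy(release_treated)

    # calibrate read allocation on the control condition
    c_p = cfg.promoter_read_share * cfg.reads_per_sample / wp_c.sum()
    c_b = (1.0 - cfg.promoter_read_share) * cfg.reads_per_sample / wb_c.sum()
    mu_p = {CONTROL: c_p * wp_c, TREATED: c_p * wp_t}
    mu_b = {CONTROL: c_b * wb_c, TREATED: c_b * wb_t}

    # --- ground truth ------------------------------------------------------
    body_win_len = lengths - 599           # +500..L-100
    body_read_len = lengths - 169          # reads placed over +70..L-100
    def true_pi(cond):
        prom_density = mu_p[cond] / 150.0  # -50..+100 window holds all paused reads
        body_density = mu_b[cond] / body_read_len
        return prom_density / body_density

    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "is_target": is_target,
        "initiation": initiation,
        "release_control": release,
        "release_treated": release_treated,
        "true_log2_body_change": np.log2((release_treated / (release_treated + t))
                                         / (release / (release + t))),
        "true_pi_control": true_pi(CONTROL),
        "true_pi_treated": true_pi(TREATED),
    })

    # --- annotation --------------------------------------------------------
    annotation = pd.DataFrame({
        "gene_id": gene_ids,
        "transcript_id": [f"{g}.t1" for g in gene_ids],
        "chrom": cfg.chrom,
        "strand": strands,
        "txStart": starts,
        "txEnd": ends,
        "cdsStart": starts,
        "cdsEnd": ends,
    })
    genes = {}
    for i, g in enumerate(gene_ids):
        plus = strands[i] == "+"
        genes[g] = GeneModel(
            gene_id=g, chrom=cfg.chrom, strand=strands[i],
            tss=int(starts[i] if plus else ends[i] - 1),
            tes=int(ends[i] - 1 if plus else starts[i]),
            cds_length=int(lengths[i]), length=int(lengths[i]),
            transcript_id=f"{g}.t1",
            short=bool(lengths[i] < cfg.min_gene_length))

    # --- reads per sample --------------------------------------------------
    tss = np.where(strands == "+", starts, ends - 1)
    direction = np.where(strands == "+", 1, -1)
    seqs = np.random.SeedSequence(cfg.seed).spawn(len(cfg.sample_ids) + 1)[1:]

    tracks: dict[str, EndCountTrack] = {}
    sample_rows = []
    for j, (sid, cond) in enumerate(zip(cfg.sample_ids, cfg.conditions)):
        rng = np.random.default_rng(seqs[j])
        kp = _nb_draw(rng, lambdas[j] * mu_p[cond], cfg.nb_dispersion)
        kb = _nb_draw(rng, lambdas[j] * mu_b[cond], cfg.nb_dispersion)

        # paused reads: uniform relative +20..+60
        gp = np.repeat(np.arange(cfg.n_genes), kp)
        rel_p = rng.integers(20, 61, size=gp.size)
        pos_p = tss[gp] + (rel_p - 1) * direction[gp]
        # elongating reads: uniform relative +70..L-100
        gb = np.repeat(np.arange(cfg.n_genes), kb)
        rel_b = rng.integers(70, body_read_len[gb] + 70)
        pos_b = tss[gb] + (rel_b - 1) * direction[gb]

        gidx = np.concatenate((gp, gb))
        pos = np.concatenate((pos_p, pos_b))
        positions = {}
        for s in ("+", "-"):
            m = strands[gidx] == s
            if m.any():
                positions[(cfg.chrom, s)] = pos[m]
        spike_total = int(rng.poisson(cfg.spike_reads_base * lambdas[j]))
        track = EndCountTrack.from_positions(sid, positions, spike_total)
        tracks[sid] = track
        sample_rows.append({
            "sample": sid, "condition": cond,
            "replicate": j % cfg.replicates + 1,
            "depth_distortion": lambdas[j],
            "primary_total": track.primary_total,
            "spike_total": spike_total,
        })
        # keep spike read positions for file output
        track._spike_positions = np.sort(
            rng.integers(0, cfg.spike_chrom_length, size=spike_total))

    samples = pd.DataFrame(sample_rows)
    result = SimulatedExperiment(cfg, annotation, genes, tracks, samples, truth)
    if outdir is not None:
        _write_experiment(result, outdir)
    return result


def _write_experiment(result: SimulatedExperiment, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    cfg = result.config
    p = {}
    p["annotation"] = os.path.join(outdir, "annotation.tsv")
    write_table(result.annotation, p["annotation"], seed=cfg.seed)
    p["truth"] = os.path.join(outdir, "ground_truth.tsv")
    write_table(result.truth, p["truth"], seed=cfg.seed)
    p["samples"] = os.path.join(outdir, "samples.tsv")
    write_table(result.samples, p["samples"], seed=cfg.seed)
    for sid, track in result.tracks.items():
        path = os.path.join(outdir, f"{sid}.bed")
        p[sid] = path
        with open(path, "w") as fh:
            i = 0
            for (chrom, strand) in sorted(track.keys()):
                pos, cnt = track.arrays(chrom, strand)
                for x, c in zip(pos, cnt):
                    for _ in range(int(c)):
                        fh.write(f"{chrom}\t{x}\t{x + 1}\tread{i}\t0\t{strand}\n")
                        i += 1
            for x in getattr(track, "_spike_positions", ()):
                fh.write(f"{cfg.spike_chrom}\t{x}\t{x + 1}\tread{i}\t0\t+\n")
                i += 1
    result.paths = p


# ---------------------------------------------------------------------------
# ChIP/ATAC peak-count experiment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChipSimConfig:
    """Study conditions for a synthetic spike-in ChIP/ATAC peak experiment.

    Treated-sample peak mean is ``baseline * (1+gamma) * (1+delta)`` at
    target peaks (``delta`` applies only there), all scaled by the sample's
    depth distortion; spike totals are condition-independent.
    """

    n_peaks: int = 500
    n_targets: int = 50
    replicates: int = 2
    baseline_meanlog: float = 5.0   # median ~150 reads/peak
    baseline_sdlog: float = 0.6
    global_gain: float = 0.0        # gamma
    target_extra_gain: float = 0.0  # delta
    nb_dispersion: float = 0.05
    depth_distortion: tuple[float, ...] | None = None
    depth_distortion_sdlog: float = 0.25
    spike_reads_base: int = 20_000
    peak_width: int = 400
    chrom: str = "chr2L"
    seed: int = 0
    #: optional explicit target mask (length n_peaks); overrides n_targets
    target_mask: tuple[bool, ...] | None = None

    def __post_init__(self):
        if self.global_gain < 0 or self.target_extra_gain < 0:
            raise ValueError("gains must be >= 0")

    @property
    def sample_ids(self) -> list[str]:
        return [f"{c}_rep{r + 1}" for c in (CONTROL, TREATED)
                for r in range(self.replicates)]

    @property
    def conditions(self) -> list[str]:
        return [CONTROL] * self.replicates + [TREATED] * self.replicates


@dataclass
class SimulatedPeaks:
    config: ChipSimConfig
    peaks: list[Interval]
    counts: pd.DataFrame           # peaks x samples
    samples: pd.DataFrame
    truth: pd.DataFrame


def simulate_chip_peaks(config: ChipSimConfig) -> SimulatedPeaks:
    """Simulate per-peak read counts for a spike-in ChIP/ATAC contrast."""
    cfg = config
    master = np.random.default_rng(np.random.SeedSequence(cfg.seed))

    baseline = master.lognormal(cfg.baseline_meanlog, cfg.baseline_sdlog,
                                size=cfg.n_peaks)
    if cfg.target_mask is not None:
        is_target = np.asarray(cfg.target_mask, dtype=bool)
        if is_target.shape != (cfg.n_peaks,):
            raise ValueError("target_mask length must equal n_peaks")
    else:
        is_target = np.zeros(cfg.n_peaks, dtype=bool)
        is_target[master.choice(cfg.n_peaks, size=cfg.n_targets, replace=False)] = True
    lambdas = _draw_lambdas(cfg, master)

    gain = (1.0 + cfg.global_gain) * (1.0 + cfg.target_extra_gain * is_target)
    mu = {CONTROL: baseline, TREATED: baseline * gain}

    peak_ids = [f"peak{i:05d}" for i in range(cfg.n_peaks)]
    peaks = [Interval(cfg.chrom, 10_000 * i, 10_000 * i + cfg.peak_width, name=pid)
             for i, pid in enumerate(peak_ids)]

    seqs = np.random.SeedSequence(cfg.seed).spawn(len(cfg.sample_ids) + 1)[1:]
    counts = {}
    sample_rows = []
    for j, (sid, cond) in enumerate(zip(cfg.sample_ids, cfg.conditions)):
        rng = np.random.default_rng(seqs[j])
        k = _nb_draw(rng, lambdas[j] * mu[cond], cfg.nb_dispersion)
        counts[sid] = k
        sample_rows.append({
            "sample": sid, "condition": cond,
            "replicate": j % cfg.replicates + 1,
            "depth_distortion": lambdas[j],
            "primary_total": int(k.sum()),
            "spike_total": int(rng.poisson(cfg.spike_reads_base * lambdas[j])),
        })

    counts_df = pd.DataFrame(counts, index=peak_ids)
    truth = pd.DataFrame({
        "peak_id": peak_ids,
        "is_target": is_target,
        "baseline": baseline,
        "true_log2_change": np.log2(gain),
    })
    return SimulatedPeaks(cfg, peaks, counts_df, pd.DataFrame(sample_rows), truth)
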