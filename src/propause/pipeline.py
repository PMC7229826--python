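"""Configuration, logging, and the one-command end-to-end run.

``run_all`` ties the stages together on a synthetic experiment: simulate ->
write/read the standard formats -> gene-body counts -> spike-normalized
differential testing -> expressed filter -> pausing indices -> metagene
window tests -> ChIP peak simulation and differential strength ->
acetylation-transcription coupling.  Every output lands under the configured
output directory together with a run manifest (parameters, package version,
input checksums), and a log records every threshold actually applied.
"""

from __future__ import annotations

import configparser
import dataclasses
import hashlib
import json
import logging
import os
import sys

import numpy as np
import pandas as pd

from . import differential, metagene, quant, regions, synthetic
from .formats_io import __version__, read_end_counts, read_gene_annotation, write_table
from .synthetic import CONTROL, TREATED, ChipSimConfig, SimConfig

logger = logging.getLogger("propause")


@dataclasses.dataclass
class RunConfig:
    """Thresholds and simulation settings for an end-to-end run.

    Threshold defaults are the study's printed values: expressed genes at
    mean log2(TPM+1) > 3, up/down calls at FDR < 0.1, unchanged at
    FDR > 0.5, acetylation-gain sets at > 1.5-fold.
    """

    seed: int = 0
    expressed_log2_tpm: float = 3.0
    up_down_fdr: float = 0.1
    unchanged_fdr: float = 0.5
    gain_fold: float = 1.5
    spike_prefix: str = "spike_"
    pause_window: tuple[int, int] = (1, 70)
    early_body_window: tuple[int, int] = (70, 200)
    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    chip_global_gain: float = 1.0
    chip_target_extra_gain: float = 1.5

    def __post_init__(self):
        for name in ("up_down_fdr", "unchanged_fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


def load_config(path, seed: int | None = None) -> RunConfig:
    """Read a flat key=value config with [run] / [simulate] / [chip] sections.

    Unknown keys are an error naming the offending key; every key is
    optional and defaults to the study's values.
    """
    parser = configparser.ConfigParser()
    with open(path) as fh:
        parser.read_file(fh)
    run_kwargs, sim_kwargs, chip = {}, {}, {}
    run_fields = {f.name: f.type for f in dataclasses.fields(RunConfig)
                  if f.name not in ("sim",)}
    sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
    for section in parser.sections():
        for key, value in parser.items(section):
            if section == "simulate":
                if key not in sim_fields:
                    raise ValueError(f"unknown config key [simulate] {key}")
                sim_kwargs[key] = _coerce(value)
            elif section in ("run", "DEFAULT"):
                if key == "chip_global_gain" or key == "chip_target_extra_gain":
                    chip[key] = float(value)
                elif key not in run_fields:
                    raise ValueError(f"unknown config key [run] {key}")
                else:
                    run_kwargs[key] = _coerce(value)
            elif section == "chip":
                chip["chip_" + key] = float(value)
            else:
                raise ValueError(f"unknown config section [{section}]")
    run_kwargs.update(chip)
    if seed is not None:
        run_kwargs["seed"] = seed
    cfg_seed = run_kwargs.get("seed", sim_kwargs.get("seed", 0))
    run_kwargs["seed"] = cfg_seed
    sim_kwargs["seed"] = cfg_seed
    if "pause_window" in run_kwargs:
        run_kwargs["pause_window"] = _parse_window(run_kwargs["pause_window"])
    if "early_body_window" in run_kwargs:
        run_kwargs["early_body_window"] = _parse_window(run_kwargs["early_body_window"])
    return RunConfig(sim=SimConfig(**sim_kwargs), **run_kwargs)


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    return value


def _parse_window(value) -> tuple[int, int]:
    if isinstance(value, tuple):
        return value
    lo, hi = str(value).replace(":", " ").split()
    return int(lo), int(hi)


def setup_logging(outdir: str | None = None, level: int = logging.INFO) -> None:
    """Structured logging to console, plus a run.log under outdir if given."""
    root = logging.getLogger("propause")
    root.setLevel(level)
    root.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    root.addHandler(sh)
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        fh = logging.FileHandler(os.path.join(outdir, "run.log"), mode="w")
        fh.setFormatter(fmt)
        root.addHandler(fh)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig, outdir: str) -> dict:
    """Run the full synthetic pipeline; returns the summary also written to
    ``outdir/summary.json``."""
    os.makedirs(outdir, exist_ok=True)
    cfg = config
    logger.info("thresholds: expressed log2TPM>%g, up/down FDR<%g, unchanged "
                "FDR>%g, gain fold>%g", cfg.expressed_log2_tpm, cfg.up_down_fdr,
                cfg.unchanged_fdr, cfg.gain_fold)

    sim_dir = os.path.join(outdir, "sim")
    sim = synthetic.simulate_experiment(cfg.sim, outdir=sim_dir)

    # read everything back through the standard formats
    genes = read_gene_annotation(sim.paths["annotation"],
                                 min_length=cfg.sim.min_gene_length)
    tracks = {sid: read_end_counts(sim.paths[sid], spike_prefix=cfg.spike_prefix,
                                   sample_id=sid)
              for sid in cfg.sim.sample_ids}
    samples = sim.samples.set_index("sample")

    # gene-body differential expression with spike-in normalization
    counts = quant.body_count_matrix(tracks, genes)
    cm = differential.CountMatrix(counts, samples)
    de = differential.run_differential(
        cm, (TREATED, CONTROL), normalization="spike",
        up_down_fdr=cfg.up_down_fdr, unchanged_fdr=cfg.unchanged_fdr)
    write_table(de.reset_index().rename(columns={"index": "gene_id"}),
                os.path.join(outdir, "differential.tsv"), seed=cfg.seed)

    # expressed-gene filter
    tpm = quant.body_tpm_matrix(counts, genes, samples["primary_total"])
    expressed = quant.filter_expressed(tpm, cfg.expressed_log2_tpm)
    logger.info("expressed genes (mean log2(TPM+1) > %g): %d of %d",
                cfg.expressed_log2_tpm, len(expressed), len(counts))

    # pausing indices per sample, mean PI per class/condition
    pi_frames = {sid: quant.pausing_table(tracks[sid], genes)
                 for sid in cfg.sim.sample_ids}
    pi_all = pd.concat(pi_frames, names=["sample"]).reset_index()
    write_table(pi_all, os.path.join(outdir, "pausing_index.tsv"), seed=cfg.seed)

    truth = sim.truth.set_index("gene_id")
    targets = truth.index[truth["is_target"]]
    cond_of = dict(zip(samples.index, samples["condition"]))
    factors = differential.spike_size_factors(samples["spike_total"])

    def mean_pi(cond, gene_set):
        vals = [pi_frames[sid].loc[pi_frames[sid].index.isin(gene_set), "pi"]
                for sid in cfg.sim.sample_ids if cond_of[sid] == cond]
        return float(np.nanmean(pd.concat(vals)))

    # metagene profiles and paired window tests on target genes
    target_genes = {g: genes[g] for g in targets if not genes[g].short}
    offsets = metagene.default_offsets(-200, 500)
    mm = metagene.metagene_profile(tracks, target_genes, cond_of, factors, offsets)
    for cond in (CONTROL, TREATED):
        write_table(mm.profile(cond), os.path.join(outdir, f"metagene_{cond}.tsv"),
                    seed=cfg.seed, condition=cond)
    pause_test = metagene.window_paired_test(mm.values[CONTROL], mm.values[TREATED],
                                             cfg.pause_window)
    body_test = metagene.window_paired_test(mm.values[CONTROL], mm.values[TREATED],
                                            cfg.early_body_window)

    # ChIP peak branch: acetylation gain concentrated at PRO-seq targets
    chip_cfg = ChipSimConfig(
        n_peaks=cfg.sim.n_genes, replicates=cfg.sim.replicates,
        global_gain=cfg.chip_global_gain,
        target_extra_gain=cfg.chip_target_extra_gain,
        nb_dispersion=cfg.sim.nb_dispersion,
        spike_reads_base=cfg.sim.spike_reads_base,
        target_mask=tuple(truth["is_target"]), seed=cfg.seed)
    chip = synthetic.simulate_chip_peaks(chip_cfg)
    chip_cm = differential.CountMatrix(chip.counts,
                                       chip.samples.set_index("sample"))
    chip_de = differential.run_differential(
        chip_cm, (TREATED, CONTROL), normalization="spike",
        up_down_fdr=cfg.up_down_fdr, unchanged_fdr=cfg.unchanged_fdr)
    write_table(chip_de.reset_index().rename(columns={"index": "peak_id"}),
                os.path.join(outdir, "chip_differential.tsv"), seed=cfg.seed)

    # coupling: acetylation change vs transcription change, gene-matched
    acetyl_lfc = chip_de["log2fc"].to_numpy()
    body_lfc = de["log2fc"].reindex(truth.index).to_numpy()
    r, rho, n_pairs = regions.fc_correlation(acetyl_lfc, body_lfc)
    gain_set = regions.threshold_gain_set(
        pd.Series(acetyl_lfc, index=truth.index), cfg.gain_fold)
    logger.info("coupling: pearson r=%.3f spearman rho=%.3f over %d genes; "
                ">%gx acetylation-gain set: %d genes", r, rho, n_pairs,
                cfg.gain_fold, len(gain_set))

    summary = {
        "n_genes": int(len(counts)),
        "n_expressed": int(len(expressed)),
        "de_classes": de["class"].value_counts().to_dict(),
        "mean_pi": {
            "targets_control": mean_pi(CONTROL, set(targets)),
            "targets_treated": mean_pi(TREATED, set(targets)),
            "others_control": mean_pi(CONTROL, set(truth.index) - set(targets)),
            "others_treated": mean_pi(TREATED, set(truth.index) - set(targets)),
        },
        "pause_window_test": dataclasses.asdict(pause_test),
        "early_body_window_test": dataclasses.asdict(body_test),
        "chip_classes": chip_de["class"].value_counts().to_dict(),
        "coupling": {"pearson_r": r, "spearman_rho": rho, "n": n_pairs},
        "acetylation_gain_genes": int(len(gain_set)),
    }
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "expressed_log2_tpm": cfg.expressed_log2_tpm,
            "up_down_fdr": cfg.up_down_fdr,
            "unchanged_fdr": cfg.unchanged_fdr,
            "gain_fold": cfg.gain_fold,
            "spike_prefix": cfg.spike_prefix,
            "sim": dataclasses.asdict(cfg.sim),
            "chip_global_gain": cfg.chip_global_gain,
            "chip_target_extra_gain": cfg.chip_target_extra_gain,
        },
        "input_checksums": {os.path.basename(p): _sha256(p)
                            for p in sorted(sim.paths.values())},
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return summary
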