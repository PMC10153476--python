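"""Configuration-driven orchestration: simulate/read -> filter -> scans ->
null calibration -> local ancestry -> polygenic test.

A run is a directory of plain-text intermediates (EIGENSTRAT data, scan and
LAD TSVs, null-fit sidecars, a JSON manifest and a log).  Each stage consumes
only files, so any stage can be re-run from the intermediates of an earlier
one.  A single global seed deterministically spawns per-stage seeds through
``numpy.random.SeedSequence``; identical config + seed yields byte-identical
outputs (the log file carries stage tags but no wall-clock timestamps for
this reason — timestamps appear on stderr only).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ancestry import ALPHA_DEFAULT, NE_DEFAULT, PSEUDOCOUNT_DEFAULT, \
    T_GENERATIONS_DEFAULT, build_hmm, cohort_lad, posterior_dosage, write_lad
from .io import ADMIXED, MESOLITHIC, NEOLITHIC, GenotypeMatrix, IntervalSet, \
    compute_frequencies, filter_sites, interpolate_genetic_positions, \
    read_eigenstrat, read_recombination_map, write_eigenstrat
from .nullfit import MIN_GAP_BP_DEFAULT, fit_gamma, qq_data, save_null, \
    spaced_subsample, tail_pvalues
from .polygenic import LAD_MATCH_CAP_BP_DEFAULT, P_THRESHOLD_DEFAULT, \
    PRUNE_WINDOW_BP_DEFAULT, ancestry_weight, lad_correlation, \
    prune_associations, read_associations
from .scan import WINDOW_SNPS_DEFAULT, f2_statistic, fadm_statistic, \
    sliding_windows, write_scan
from .simulate import SelectedLocus, SimulationConfig, simulate_cohort, \
    write_truth

logger = logging.getLogger("admixscan")

ALL_STAGES = ("data", "scan", "lad", "polygenic")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Validated run configuration; exactly one data source is active."""

    seed: int = 0
    output_dir: str = "admixscan_run"
    simulation: SimulationConfig | None = None
    inputs: dict | None = None          # geno/snp/ind [+ mappability_bed,
                                        #  recombination_map]
    min_neolithic_obs: int = 20
    maf_min: float = 0.0
    window_snps: int = WINDOW_SNPS_DEFAULT
    min_gap_bp: int = MIN_GAP_BP_DEFAULT
    alpha: float = ALPHA_DEFAULT
    t_generations: float = T_GENERATIONS_DEFAULT
    ne: float = NE_DEFAULT
    pseudocount: float = PSEUDOCOUNT_DEFAULT
    hmm_mode: str = "diploid"
    associations: str | None = None
    p_threshold: float = P_THRESHOLD_DEFAULT
    prune_window_bp: int = PRUNE_WINDOW_BP_DEFAULT
    lad_match_cap_bp: int = LAD_MATCH_CAP_BP_DEFAULT
    write_posteriors: bool = False
    stages: tuple[str, ...] = ("data", "scan", "lad")

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError("exactly one of 'simulation' and 'inputs' "
                             "must be configured")
        if self.inputs is not None:
            missing = {"geno", "snp", "ind"} - set(self.inputs)
            if missing:
                raise ValueError(f"inputs block lacks {sorted(missing)}")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if "polygenic" in self.stages and not self.associations:
            raise ValueError("polygenic stage requested without an "
                             "association table")
        if self.window_snps % 2 == 0 or self.window_snps < 1:
            raise ValueError("window_snps must be odd and positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulation", None)
        if sim is not None:
            loci = tuple(SelectedLocus(str(l["chromosome"]),
                                       int(l["position_bp"]),
                                       float(l["ancestry_shift"]),
                                       float(l.get("frequency_shift", 0.0)))
                         for l in sim.pop("selected_loci", []))
            if "ancestral_freq_range" in sim:
                sim["ancestral_freq_range"] = tuple(sim["ancestral_freq_range"])
            sim = SimulationConfig(selected_loci=loci, **sim)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(simulation=sim, **raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


# ---------------------------------------------------------------------------
# Stage logic
# ---------------------------------------------------------------------------

def _stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31, derived from the global one."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _setup_run_logging(run_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(run_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("[%(levelname)s] %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    return handler


class PipelineRun:
    """Stage executor bound to one run directory."""

    def __init__(self, config: PipelineConfig, run_dir: str | Path | None = None):
        self.config = config
        self.run_dir = Path(run_dir or config.output_dir)
        self.run_dir.mkdir(parents=True, exist_ok=True)
        self._data: GenotypeMatrix | None = None
        self._filtered: GenotypeMatrix | None = None

    # -- data ---------------------------------------------------------------
    def stage_data(self) -> GenotypeMatrix:
        cfg = self.config
        prefix = self.run_dir / "data"
        if prefix.with_suffix(".geno").exists():
            logger.info("[data] reusing existing %s.{geno,snp,ind}", prefix)
            self._data = read_eigenstrat(prefix.with_suffix(".geno"),
                                         prefix.with_suffix(".snp"),
                                         prefix.with_suffix(".ind"))
        elif cfg.simulation is not None:
            sim_cfg = dataclasses.replace(
                cfg.simulation, seed=_stage_seed(cfg.seed, "simulate"))
            logger.info("[data] simulating cohort (seed %d)", sim_cfg.seed)
            result = simulate_cohort(sim_cfg)
            self._data = result.genotypes
            write_eigenstrat(result.genotypes, prefix)
            write_truth(result.truth, prefix)
        else:
            logger.info("[data] reading EIGENSTRAT inputs")
            gm = read_eigenstrat(cfg.inputs["geno"], cfg.inputs["snp"],
                                 cfg.inputs["ind"])
            recmap_path = cfg.inputs.get("recombination_map")
            if recmap_path or np.ptp(gm.snps.genetic_pos) == 0:
                recmap = (read_recombination_map(recmap_path)
                          if recmap_path else None)
                gm.snps.genetic_pos = interpolate_genetic_positions(
                    gm.snps, recmap)
            self._data = gm
            write_eigenstrat(gm, prefix)
        return self._data

    def _get_data(self) -> GenotypeMatrix:
        if self._data is None:
            self.stage_data()
        return self._data

    def _get_filtered(self) -> GenotypeMatrix:
        if self._filtered is not None:
            return self._filtered
        cfg = self.config
        mappability = None
        if cfg.inputs and cfg.inputs.get("mappability_bed"):
            mappability = IntervalSet.from_bed(cfg.inputs["mappability_bed"])
        self._filtered = filter_sites(self._get_data(), mappability,
                                      min_neolithic_obs=cfg.min_neolithic_obs,
                                      maf_min=cfg.maf_min)
        return self._filtered

    # -- scans --------------------------------------------------------------
    def stage_scan(self) -> dict[str, pd.DataFrame]:
        cfg = self.config
        gm = self._get_filtered()
        freqs = compute_frequencies(gm)
        pops = set(freqs.populations)
        per_snp = {}
        if {MESOLITHIC, NEOLITHIC} <= pops:
            per_snp["f2_mes_neo"] = f2_statistic(freqs.freq(MESOLITHIC),
                                                 freqs.freq(NEOLITHIC))
        if {NEOLITHIC, ADMIXED} <= pops:
            per_snp["f2_neo_adm"] = f2_statistic(freqs.freq(NEOLITHIC),
                                                 freqs.freq(ADMIXED))
        if {MESOLITHIC, NEOLITHIC, ADMIXED} <= pops:
            per_snp["fadm"] = fadm_statistic(freqs.freq(ADMIXED),
                                             freqs.freq(MESOLITHIC),
                                             freqs.freq(NEOLITHIC), cfg.alpha)
        out = {}
        for name, stat in per_snp.items():
            logger.info("[scan] %s: windowing and null calibration", name)
            win = sliding_windows(stat, gm.snps, window_snps=cfg.window_snps)
            if len(win):
                null = spaced_subsample(win, min_gap_bp=cfg.min_gap_bp)
                try:
                    fit = fit_gamma(null)
                except ValueError as exc:
                    logger.warning("[scan] %s: no gamma calibration (%s)",
                                   name, exc)
                else:
                    win = win.copy()
                    win["pvalue"] = tail_pvalues(fit, win["value"].to_numpy())
                    save_null(null, fit, self.run_dir / f"scan_{name}")
                    qq_data(win["pvalue"].to_numpy()).to_csv(
                        self.run_dir / f"scan_{name}.qq.tsv", sep="\t",
                        index=False, float_format="%.10g")
            write_scan(win, self.run_dir / f"scan_{name}.tsv")
            out[name] = win
        return out

    # -- local ancestry -----------------------------------------------------
    def stage_lad(self):
        cfg = self.config
        gm = self._get_filtered()
        freqs = compute_frequencies(gm)
        hmm = build_hmm(alpha=cfg.alpha, t_generations=cfg.t_generations,
                        ne=cfg.ne, snps=gm.snps, panel_freqs=freqs,
                        mode=cfg.hmm_mode, pseudocount=cfg.pseudocount)
        admixed = gm.population_mask(ADMIXED)
        if not admixed.any():
            raise ValueError("no ADMIXED individuals for local ancestry")
        logger.info("[lad] decoding %d admixed individuals at %d sites",
                    int(admixed.sum()), gm.n_snps)
        track = posterior_dosage(hmm, gm.calls[:, admixed])
        lad = cohort_lad(track, gm.snps, window_snps=cfg.window_snps,
                         min_gap_bp=cfg.min_gap_bp)
        write_lad(lad, self.run_dir / "lad.tsv")
        lad.null.windows.to_csv(self.run_dir / "lad.null.tsv", sep="\t",
                                index=False, float_format="%.10g")
        if cfg.write_posteriors:
            frame = pd.DataFrame(
                track.fraction,
                columns=list(gm.individual_ids[admixed]))
            frame.insert(0, "chromosome", gm.snps.chromosome)
            frame.insert(1, "position_bp", gm.snps.position_bp)
            frame.to_csv(self.run_dir / "posterior_fractions.tsv", sep="\t",
                         index=False, float_format="%.6g")
        return lad

    # -- polygenic ----------------------------------------------------------
    def stage_polygenic(self, lad) -> pd.DataFrame:
        cfg = self.config
        gm = self._get_filtered()
        freqs = compute_frequencies(gm)
        assoc = read_associations(cfg.associations)
        traits = (assoc["trait"].unique() if "trait" in assoc.columns
                  else ["trait"])
        rows, pair_frames = [], []
        for trait in traits:
            sub = (assoc[assoc["trait"] == trait]
                   if "trait" in assoc.columns else assoc)
            pruned = prune_associations(sub, p_threshold=cfg.p_threshold,
                                        window_bp=cfg.prune_window_bp)
            weighted = ancestry_weight(pruned, freqs, gm.snps)
            result = lad_correlation(weighted, lad, trait=str(trait),
                                     max_match_bp=cfg.lad_match_cap_bp)
            rows.append((result.trait, result.r, result.p, result.n_snps,
                         result.weighted_sum))
            weighted = weighted.copy()
            weighted["trait"] = trait
            pair_frames.append(weighted)
        results = pd.DataFrame(rows, columns=["trait", "pearson_r", "p",
                                              "n_snps", "weighted_sum"])
        results.to_csv(self.run_dir / "polygenic_results.tsv", sep="\t",
                       index=False, float_format="%.10g")
        pd.concat(pair_frames, ignore_index=True).to_csv(
            self.run_dir / "polygenic_weights.tsv", sep="\t", index=False,
            float_format="%.10g")
        return results

    def write_manifest(self, stages_run: list[str]) -> None:
        cfg = self.config.to_dict()
        cfg.pop("output_dir", None)   # keep reruns byte-identical across dirs
        blob = json.dumps(cfg, sort_keys=True, default=str)
        manifest = {
            "package": "admixscan",
            "version": __version__,
            "seed": self.config.seed,
            "stage_seeds": {s: _stage_seed(self.config.seed, s)
                            for s in ("simulate",)},
            "config": cfg,
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "stages": stages_run,
        }
        (self.run_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(config: PipelineConfig,
                 run_dir: str | Path | None = None) -> Path:
    """Execute the configured stages in dependency order; returns the run dir."""
    run = PipelineRun(config, run_dir)
    handler = _setup_run_logging(run.run_dir)
    try:
        stages = list(dict.fromkeys(("data",) + tuple(config.stages)))
        run.stage_data()
        if "scan" in stages:
            run.stage_scan()
        lad = None
        if "lad" in stages or "polygenic" in stages:
            lad = run.stage_lad()
        if "polygenic" in stages:
            run.stage_polygenic(lad)
        run.write_manifest(stages)
    except Exception:
        logger.exception("pipeline stage failed")
        raise
    finally:
        handler.close()
        logger.removeHandler(handler)
    return run.run_dir


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def summarize_run(run_dir: str | Path, top_n: int = 10,
                  annotations: IntervalSet | None = None
                  ) -> dict[str, pd.DataFrame]:
    """Report tables for a completed run: top windows, QQ data, LAD extremes."""
    run_dir = Path(run_dir)
    if not (run_dir / "manifest.json").exists():
        raise ValueError(f"{run_dir} is not a completed run "
                         "(manifest.json missing)")
    report: dict[str, pd.DataFrame] = {}
    for scan_path in sorted(run_dir.glob("scan_*.tsv")):
        name = scan_path.stem
        if name.endswith((".null", ".qq")):
            continue
        scan = pd.read_csv(scan_path, sep="\t", dtype={"chromosome": str})
        if len(scan) == 0 or "pvalue" not in scan.columns:
            top = scan.head(0)
        else:
            top = scan.nsmallest(top_n, "pvalue").copy()
            if annotations is not None:
                top["annotated"] = annotations.contains_positions(
                    top["chromosome"].to_numpy(dtype=object),
                    top["center_bp"].to_numpy())
        top.to_csv(run_dir / f"report_{name}_top.tsv", sep="\t", index=False,
                   float_format="%.10g")
        report[name] = top
    lad_path = run_dir / "lad.tsv"
    if lad_path.exists():
        lad = pd.read_csv(lad_path, sep="\t", dtype={"chromosome": str})
        mes = lad.nlargest(top_n, "z").assign(direction="mesolithic_excess")
        neo = lad.nsmallest(top_n, "z").assign(direction="neolithic_excess")
        extremes = pd.concat([mes, neo], ignore_index=True)
        extremes.to_csv(run_dir / "report_lad_extremes.tsv", sep="\t",
                        index=False, float_format="%.10g")
        report["lad_extremes"] = extremes
    return report
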