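"""Full-analysis orchestration: one native structure, one candidate pool,
many experimental conditions.

The pipeline mirrors the pool-selection workflow for a flexible
multi-domain protein: a single simulation provides the candidate
conformations, which are scored independently against each condition's
experimental curve (apo / nucleotide-bound states share the pool).  Stages
communicate exclusively through files in the output directory, and a run
manifest records every stage's parameters, counts and output hashes, which
makes runs resumable and tamper-evident.

Stage order: ``setup`` (topology) → ``sampling`` (candidate pool) →
``profiles`` (Debye curves) → ``score`` (per-condition χ², filter, P(Rg),
representatives) → ``fit`` (per-condition ensemble search) → ``crosstab``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import ensemble as ens
from .curve import read_curve, write_curve
from .forcefield import ForcefieldParams, Topology, build_topology
from .sampler import SamplerParams, run_sampling
from .saxs import debye_profile
from .structure import (
    ConformationSet,
    read_conformations,
    read_pdb,
    write_conformations,
)
from .synthetic import conformer_family

__all__ = ["RunConfig", "PipelineStageError", "run_full", "resume", "STAGES"]

STAGES = ("setup", "sampling", "profiles", "score", "fit", "crosstab")


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name for attribution."""

    def __init__(self, stage: str, cause: BaseException) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclasses.dataclass
class RunConfig:
    """Flat configuration for a full pipeline run (YAML-serializable)."""

    structure: str
    domain_map: dict[str, Any]
    conditions: dict[str, str]  # condition name -> experimental curve path
    output_dir: str
    sampling_mode: str = "sampled"  # "sampled" (Langevin) or "hinge"
    n_conformers: int = 400  # hinge mode pool size
    hinge_max_angle: float = 2.5
    sampler: dict[str, Any] = dataclasses.field(default_factory=dict)
    forcefield: dict[str, Any] = dataclasses.field(default_factory=dict)
    saxs_mode: str = "vacuum"
    filter_fraction: float = 0.05
    bin_width: float = 0.25
    prominence_frac: float = 0.05
    k_per_peak: int = 4
    min_rmsd: float = 2.0
    n_peaks: int = 3
    weight_step: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.filter_fraction < 1.0:
            raise ValueError("filter_fraction must lie in (0, 1)")
        if not self.conditions:
            raise ValueError("at least one experimental condition required")
        # canonical JSON-shaped form (tuples become lists) so that configs
        # round-trip through YAML/JSON without spurious differences
        self.domain_map = json.loads(json.dumps(self.domain_map))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(**doc)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Run:
    """Stage executor bound to one output directory."""

    def __init__(self, config: RunConfig) -> None:
        self.config = config
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict[str, Any] = {"config": config.to_dict(), "stages": {}}

    # -- bookkeeping -------------------------------------------------------
    def _record(self, stage: str, outputs: list[Path], counts: dict[str, int]) -> None:
        self.manifest["stages"][stage] = {
            "outputs": {p.name: _sha256(p) for p in outputs},
            "counts": counts,
        }
        self._write_manifest()

    def _write_manifest(self) -> None:
        (self.out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=1, sort_keys=True)
        )

    def verify(self, upto_stage: str | None = None) -> None:
        """Check recorded output hashes for all stages before ``upto_stage``."""
        for stage in STAGES:
            if stage == upto_stage:
                break
            entry = self.manifest["stages"].get(stage)
            if entry is None:
                raise ValueError(f"stage {stage!r} missing from manifest")
            for name, digest in entry["outputs"].items():
                path = self.out / name
                if not path.exists():
                    raise ValueError(f"missing output {name} of stage {stage!r}")
                if _sha256(path) != digest:
                    raise ValueError(
                        f"output {name} of stage {stage!r} does not match its "
                        "recorded hash; refusing to resume on tampered inputs"
                    )

    # -- stages ------------------------------------------------------------
    def stage_setup(self) -> None:
        cfg = self.config
        structure = read_pdb(cfg.structure, cfg.domain_map)
        params = ForcefieldParams(**cfg.forcefield)
        topo = build_topology(structure, params)
        topo.to_json(self.out / "topology.json")
        self._record(
            "setup",
            [self.out / "topology.json"],
            {
                "n_atoms": structure.n_atoms,
                "n_contacts": len(topo.contacts),
                "n_bonds": len(topo.bonds),
            },
        )

    def stage_sampling(self) -> None:
        cfg = self.config
        structure = read_pdb(cfg.structure, cfg.domain_map)
        if cfg.sampling_mode == "sampled":
            topo = Topology.from_json(self.out / "topology.json")
            sp = SamplerParams(**{"seed": cfg.seed, **cfg.sampler})
            pool = run_sampling(topo, structure, sp)
        elif cfg.sampling_mode == "hinge":
            pool = conformer_family(
                structure,
                cfg.n_conformers,
                mode="hinge",
                seed=cfg.seed,
                max_angle=cfg.hinge_max_angle,
            )
        else:
            raise ValueError(f"unknown sampling_mode {cfg.sampling_mode!r}")
        write_conformations(self.out / "pool.pdb", pool)
        self._record("sampling", [self.out / "pool.pdb"], {"n_conformers": len(pool)})

    def _load_pool(self) -> ConformationSet:
        return read_conformations(self.out / "pool.pdb", self.config.domain_map)

    def stage_profiles(self) -> None:
        cfg = self.config
        pool = self._load_pool()
        first = read_curve(next(iter(cfg.conditions.values())))
        curves = np.stack(
            [
                debye_profile(pool[i], first.q, mode=cfg.saxs_mode).intensity
                for i in range(len(pool))
            ]
        )
        np.savez(self.out / "profiles.npz", q=first.q, intensity=curves)
        self._record(
            "profiles", [self.out / "profiles.npz"], {"n_profiles": len(curves)}
        )

    def stage_score(self) -> None:
        """Per condition: χ² for every pool conformer, low-χ² filter, P(Rg)
        with peak detection, and distinct representatives per peak."""
        cfg = self.config
        pool = self._load_pool()
        prof = np.load(self.out / "profiles.npz")
        frame_to_row = {int(f): r for r, f in enumerate(pool.frame_index)}
        outputs: list[Path] = []
        counts: dict[str, int] = {}
        for name, curve_path in cfg.conditions.items():
            exp = read_curve(curve_path)
            if len(exp.q) != len(prof["q"]) or not np.allclose(exp.q, prof["q"]):
                raise ValueError(
                    f"condition {name!r}: experimental q grid differs from the "
                    "profile grid; all conditions must share one grid"
                )
            cands = ens.score_candidates(pool, exp, curves=prof["intensity"])
            kept = ens.filter_lowest(cands, cfg.filter_fraction)
            hist = ens.prg_histogram(kept, cfg.bin_width, cfg.prominence_frac)
            groups = ens.select_representatives(
                kept, hist, cfg.k_per_peak, cfg.min_rmsd, cfg.n_peaks
            )
            score_path = self.out / f"scores_{name}.tsv"
            pd.DataFrame(
                {
                    "frame": cands.frame_index,
                    "rg": cands.rg,
                    "chi2": cands.chi2,
                    "scale": cands.scale,
                }
            ).to_csv(score_path, sep="\t", index=False, float_format="%.8g")
            hist_path = self.out / f"prg_{name}.tsv"
            pd.DataFrame(
                {
                    "rg_lo": hist.edges[:-1],
                    "rg_hi": hist.edges[1:],
                    "prob": hist.prob,
                }
            ).to_csv(hist_path, sep="\t", index=False, float_format="%.8g")
            reps_path = self.out / f"representatives_{name}.pdb"
            rep_idx = np.concatenate(groups) if groups else np.zeros(0, dtype=int)
            write_conformations(reps_path, kept.conformations.subset(rep_idx))
            groups_path = self.out / f"groups_{name}.json"
            groups_path.write_text(
                json.dumps(
                    {
                        "peaks_rg": hist.peak_centers[: cfg.n_peaks].tolist(),
                        "groups": [
                            {
                                "frames": [int(kept.frame_index[i]) for i in g],
                                "rows": [frame_to_row[int(kept.frame_index[i])] for i in g],
                            }
                            for g in groups
                        ],
                    },
                    indent=1,
                    sort_keys=True,
                )
            )
            outputs += [score_path, hist_path, reps_path, groups_path]
            counts[f"{name}_survivors"] = len(kept)
            counts[f"{name}_peaks"] = len(hist.peak_centers)
        self._record("score", outputs, counts)

    def stage_fit(self) -> None:
        """Exhaustive one-per-peak ensemble search for each condition."""
        cfg = self.config
        prof = np.load(self.out / "profiles.npz")
        outputs: list[Path] = []
        counts: dict[str, int] = {}
        for name, curve_path in cfg.conditions.items():
            exp = read_curve(curve_path)
            doc = json.loads((self.out / f"groups_{name}.json").read_text())
            group_curves = [prof["intensity"][g["rows"]] for g in doc["groups"]]
            group_ids = [np.asarray(g["frames"]) for g in doc["groups"]]
            fit, n_ens = ens.combination_search(
                exp, group_curves, group_ids, cfg.weight_step
            )
            fit_path = self.out / f"fit_{name}.json"
            fit_path.write_text(
                json.dumps(
                    {
                        "member_frames": [int(i) for i in fit.member_ids],
                        "weights": fit.weights.tolist(),
                        "chi2": fit.chi2,
                        "scale": fit.scale,
                        "ensembles_evaluated": n_ens,
                        "peaks_rg": doc["peaks_rg"],
                    },
                    indent=1,
                    sort_keys=True,
                )
            )
            comb_path = self.out / f"combined_{name}.dat"
            write_curve(comb_path, fit.combined, header=f"best-fit ensemble, {name}")
            outputs += [fit_path, comb_path]
            counts[f"{name}_ensembles"] = n_ens
        self._record("fit", outputs, counts)

    def stage_crosstab(self) -> None:
        cfg = self.config
        names = list(cfg.conditions)
        fits = []
        exps = []
        for name in names:
            doc = json.loads((self.out / f"fit_{name}.json").read_text())
            combined = read_curve(self.out / f"combined_{name}.dat")
            fits.append(
                ens.EnsembleFit(
                    member_ids=tuple(doc["member_frames"]),
                    weights=np.asarray(doc["weights"]),
                    combined=combined,
                    chi2=doc["chi2"],
                    scale=doc["scale"],
                )
            )
            exps.append(read_curve(cfg.conditions[name]))
        table = ens.cross_table(fits, exps)
        path = self.out / "crosstab.tsv"
        pd.DataFrame(table, index=names, columns=names).to_csv(
            path, sep="\t", float_format="%.8g"
        )
        self._record("crosstab", [path], {"n_conditions": len(names)})

    def execute(self, stage: str) -> None:
        fn = getattr(self, f"stage_{stage}")
        try:
            fn()
        except Exception as exc:
            raise PipelineStageError(stage, exc) from exc


def run_full(config: RunConfig) -> dict[str, Any]:
    """Execute all stages; returns the run manifest (also written to
    ``output_dir/manifest.json``)."""
    run = _Run(config)
    for stage in STAGES:
        run.execute(stage)
    return run.manifest


def resume(
    manifest_path: str | Path,
    from_stage: str | None = None,
    config_overrides: dict[str, Any] | None = None,
) -> dict[str, Any]:
    """Recompute from ``from_stage`` onward, verifying upstream outputs.

    Earlier stages' outputs must exist and match their recorded hashes;
    a mismatch (tampered or missing file) is refused with an explanation.
    ``config_overrides`` lets downstream parameters (e.g. the weight-grid
    step) be changed without recomputing upstream stages.  With
    ``from_stage=None`` the whole run is verified and returned unchanged
    (a completed run resumes as a no-op).
    """
    manifest_path = Path(manifest_path)
    doc = json.loads(manifest_path.read_text())
    config = RunConfig(**{**doc["config"], **(config_overrides or {})})
    doc["config"] = config.to_dict()
    run = _Run(config)
    run.manifest = doc
    if from_stage is None:
        run.verify(upto_stage=None)
        return run.manifest
    if from_stage not in STAGES:
        raise ValueError(f"unknown stage {from_stage!r}; stages are {STAGES}")
    run.verify(upto_stage=from_stage)
    started = False
    for stage in STAGES:
        if stage == from_stage:
            started = True
        if started:
            run.execute(stage)
    return run.manifest
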