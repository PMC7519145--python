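"""Config-driven pipeline: generate → fit → cross-validate → simulate →
analyze, with a provenance manifest and idempotent stage re-runs."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import stability, validate
from .gibbs import build_model, default_priors, gibbs_fit, variance_components
from .simulate import SimulationGrid, means_matrix, simulate_performance, summarize_simulation
from .synth import GeneratorConfig, generate_dataset
from .trialdata import assign_folds
from .validate import ChainConfig

log = logging.getLogger("gxesim")

STAGES = ("generate", "fit", "cv", "simulate", "analyze")


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs; loadable from YAML."""

    output_dir: str = "gxesim_run"
    seed: int = 0
    model: str = "TGW-GxW"
    generator: dict = field(default_factory=dict)  # GeneratorConfig overrides
    chain: dict = field(default_factory=lambda: {"n_iter": 3000, "burn_in": 500, "thin": 5})
    cv: dict = field(default_factory=lambda: {"k": 5, "scheme": "by-trial", "models": ["TL", "TGW", "TGW-GxW"]})
    grid: dict = field(default_factory=lambda: {"locations": 4, "years": 3, "cultivars": 8})

    def __post_init__(self) -> None:
        from .gibbs import MODEL_TERMS

        if self.model.replace("×", "x").replace("G×W", "GxW") not in MODEL_TERMS:
            raise ValueError(f"unknown model {self.model!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class PipelineRun:
    """Stage executor with manifest-based skipping."""

    def __init__(self, cfg: PipelineConfig, force: bool = False):
        self.cfg = cfg
        self.force = force
        self.out = Path(cfg.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        self.manifest = (
            json.loads(self.manifest_path.read_text()) if self.manifest_path.exists() else {"stages": {}}
        )
        self.manifest["config"] = asdict(cfg)
        self._data = None
        self._chain = ChainConfig(**cfg.chain)

    # --- helpers --------------------------------------------------------
    def _done(self, stage: str) -> bool:
        info = self.manifest["stages"].get(stage)
        if not info or self.force:
            return False
        return all((self.out / f).exists() for f in info["outputs"])

    def _record(self, stage: str, outputs: list[str], t0: float) -> None:
        self.manifest["stages"][stage] = {
            "outputs": outputs,
            "hashes": {f: _hash_file(self.out / f) for f in outputs},
            "seconds": round(time.time() - t0, 2),
            "seed": self.cfg.seed,
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2, default=str))

    def _dataset(self):
        if self._data is None:
            gen = GeneratorConfig(seed=self.cfg.seed, **self.cfg.generator)
            self._data = generate_dataset(gen)
        return self._data

    # --- stages ---------------------------------------------------------
    def stage_generate(self) -> list[str]:
        sd = self._dataset()
        sd.dataset.to_csv(self.out / "phenotypes.csv")
        sd.genotypes.dosages.to_csv(self.out / "genotypes.csv")
        sd.ecs.to_csv(self.out / "ecs.csv")
        rows = []
        for (year, loc), w in sd.weather.items():
            df = w.data[["date", "tmin", "tmax", "radiation", "rain"]].copy()
            df.insert(0, "location", loc)
            df.insert(0, "harvest_year", year)
            rows.append(df)
        pd.concat(rows).to_csv(self.out / "weather.csv", index=False)
        return ["phenotypes.csv", "genotypes.csv", "ecs.csv", "weather.csv"]

    def stage_fit(self) -> list[str]:
        sd = self._dataset()
        design = build_model(self.cfg.model, sd.dataset.records, G=sd.G, Om=sd.Om)
        ps = gibbs_fit(
            design, default_priors(design, r2=self._chain.r2, df0=self._chain.df0),
            n_iter=self._chain.n_iter, burn_in=self._chain.burn_in,
            thin=self._chain.thin, seed=self.cfg.seed, store_effects=False,
        )
        variance_components(ps).to_csv(self.out / "variance_components.csv", index_label="term")
        return ["variance_components.csv"]

    def stage_cv(self) -> list[str]:
        sd = self._dataset()
        folds = assign_folds(
            sd.dataset, scheme=self.cfg.cv["scheme"], k=self.cfg.cv["k"], seed=self.cfg.seed
        )
        results = {}
        for model in self.cfg.cv["models"]:
            res = validate.leave_trial_out_cv(
                model, sd.dataset, folds, G=sd.G, Om=sd.Om, chain=self._chain, seed=self.cfg.seed
            )
            results[model] = res
        pd.concat(
            {m: r.table.assign(model=m) for m, r in results.items()}, ignore_index=True
        ).to_csv(self.out / "cv_results.csv", index=False)
        comp = validate.compare_models(results)
        pd.DataFrame({"mean_r": comp.means, "letters": comp.letters[comp.means.index]}).to_csv(
            self.out / "model_comparison.csv", index_label="model"
        )
        return ["cv_results.csv", "model_comparison.csv"]

    def _grid(self, sd) -> SimulationGrid:
        g = self.cfg.grid
        return SimulationGrid(
            years=sd.dataset.years[: g["years"]],
            locations=sd.dataset.locations[: g["locations"]],
            cultivars=sd.dataset.cultivars[: g["cultivars"]],
        )

    def stage_simulate(self) -> list[str]:
        sd = self._dataset()
        grid = self._grid(sd)
        records = pd.concat(
            [sd.dataset.records, grid.grid_records()], ignore_index=True
        ).drop_duplicates(["year", "location", "cultivar"], keep="first")
        design = build_model(self.cfg.model, records, G=sd.G, Om=sd.Om)
        ps = gibbs_fit(
            design, default_priors(design, r2=self._chain.r2, df0=self._chain.df0),
            n_iter=self._chain.n_iter, burn_in=self._chain.burn_in,
            thin=self._chain.thin, seed=self.cfg.seed,
        )
        sp = simulate_performance(ps, grid)
        summarize_simulation(sp).to_csv(self.out / "simulation_summary.csv", index=False)
        means_matrix(sp).to_csv(self.out / "simulated_means.csv", index_label="cultivar")
        log.info("simulated %d values (%d cells × %d samples)", sp.n_values, grid.n_cells, sp.B)
        return ["simulation_summary.csv", "simulated_means.csv"]

    def stage_analyze(self) -> list[str]:
        sd = self._dataset()
        path = self.out / "simulated_means.csv"
        if not path.exists():
            raise RuntimeError("missing upstream artifact simulated_means.csv; run 'simulate' first")
        M = pd.read_csv(path, index_col="cultivar")
        fw = stability.fw_two_step(M, G=sd.G, chain=self._chain, seed=self.cfg.seed)
        fw.to_csv(self.out / "fw_coefficients.csv")
        sreg = stability.sreg_biplot(M)
        sreg.scores.to_csv(self.out / "sreg_scores.csv", index_label="cultivar")
        sreg.loadings.to_csv(self.out / "sreg_loadings.csv", index_label="location")
        clus = stability.cluster_means(M)
        pd.DataFrame(
            {
                "axis": ["cultivars"] * len(clus["cultivars"]["order"])
                + ["locations"] * len(clus["locations"]["order"]),
                "label": clus["cultivars"]["order"] + clus["locations"]["order"],
            }
        ).to_csv(self.out / "cluster_orders.csv", index=False)
        outputs = ["fw_coefficients.csv", "sreg_scores.csv", "sreg_loadings.csv", "cluster_orders.csv"]
        outputs += self._figures(M, sreg, clus)
        return outputs

    def _figures(self, M, sreg, clus) -> list[str]:
        """Heatmap (cluster-ordered) and SREG biplot as PNGs."""
        try:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
        except ImportError:  # plotting is optional
            log.warning("matplotlib unavailable; skipping figures")
            return []
        ordered = M.loc[clus["cultivars"]["order"], clus["locations"]["order"]]
        fig, ax = plt.subplots(figsize=(7, 6))
        im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="viridis")
        ax.set_xticks(range(ordered.shape[1]), ordered.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(ordered.shape[0]), ordered.index, fontsize=6)
        fig.colorbar(im, label="predicted yield (t/ha)")
        ax.set_title("Simulated cultivar × location means")
        fig.tight_layout()
        fig.savefig(self.out / "means_heatmap.png", dpi=120)
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(6, 6))
        sc, ld = sreg.scores, sreg.loadings
        ax.scatter(sc["PC1"], sc["PC2"], s=12, color="tab:blue")
        for name, row in sc.iterrows():
            ax.annotate(str(name), (row["PC1"], row["PC2"]), fontsize=6)
        scale = float(np.abs(sc[["PC1", "PC2"]]).max().max())
        for name, row in ld.iterrows():
            ax.arrow(0, 0, row["PC1"] * scale, row["PC2"] * scale,
                     color="tab:red", alpha=0.5, head_width=scale * 0.02)
            ax.annotate(str(name), (row["PC1"] * scale, row["PC2"] * scale),
                        fontsize=6, color="tab:red")
        pct = 100 * sreg.variance_explained
        ax.set_xlabel(f"PC1 ({pct[0]:.1f}%)")
        ax.set_ylabel(f"PC2 ({pct[1]:.1f}%)")
        ax.set_title("SREG biplot")
        fig.tight_layout()
        fig.savefig(self.out / "sreg_biplot.png", dpi=120)
        plt.close(fig)
        return ["means_heatmap.png", "sreg_biplot.png"]

    def run(self, stages: list[str] | None = None) -> dict:
        stages = list(stages or STAGES)
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for stage in STAGES:
            if stage not in stages:
                continue
            if self._done(stage):
                log.info("stage %s: up to date, skipping", stage)
                continue
            t0 = time.time()
            log.info("stage %s: running", stage)
            outputs = getattr(self, f"stage_{stage}")()
            self._record(stage, outputs, t0)
        return self.manifest


def run_pipeline(cfg: PipelineConfig, stages: list[str] | None = None, force: bool = False) -> dict:
    """Execute the requested stages in dependency order; returns the manifest."""
    return PipelineRun(cfg, force=force).run(stages)
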