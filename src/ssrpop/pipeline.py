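"""End-to-end orchestration of the landrace diversity analysis.

One call (or the ``ssrpop all`` command) runs, in order: panel simulation or
loading; MLG census and genotype accumulation; per-locus marker indices;
admixture battery with Evanno delta-K and membership assignment (run on one
representative per MLG, then propagated to duplicates); per-stratum
diversity tables for genetic groups, regions and climate stages; pairwise
Nei distances; the Bruvo-distance minimum spanning network; one-level AMOVA
per stratification (admixed accessions excluded from the genetic-group
analysis); Mantel tests of genetic vs geographic (ln(1+km)) and genetic vs
trait distance; the Shannon-Weaver H' table; and per-cluster trait means
with ANOVA letters.  Every stage writes a delimited table into the run
directory and a JSON manifest records config, seeds, versions and wall
times.

Stage seeds are derived from the root seed by stable hashing of the stage
name, so any stage is independently reproducible.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .admixture import ADMIXED, AdmixtureModel, SamplerConfig, assign_membership
from .amova import amova_one_level, amova_report
from .distances import (
    bruvo_matrix,
    genotypic_sq_matrix,
    geographic_distance,
    mantel_test,
    minimum_spanning_network,
    msn_tables,
    nei_matrix,
    trait_distance,
)
from .io import (
    DEFAULT_TRAITS,
    GenotypeMatrix,
    TraitMatrix,
    metadata_frame,
    read_genotypes,
    read_metadata,
    read_traits,
    write_structure_format,
)
from .markers import genotype_accumulation, identify_mlgs, locus_indices, stratum_diversity
from .morpho import cluster_trait_means, compare_means, diversity_table
from .simulate import SimulationConfig, simulate_panel

logger = logging.getLogger(__name__)


def stage_seed(root_seed: int, stage: str) -> int:
    """Per-stage seed: stable hash of the stage name mixed with the root."""
    return (int(root_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    outdir: Path
    seed: int
    simulation: SimulationConfig | None = None
    genotypes_path: Path | None = None
    traits_path: Path | None = None
    metadata_path: Path | None = None
    locus_info: list | None = None
    sampler: SamplerConfig = field(default_factory=SamplerConfig.desk)
    k_range: tuple[int, ...] = tuple(range(1, 6))
    n_perm: int = 999
    accumulation_perm: int = 100
    membership_threshold: float = 0.75

    def __post_init__(self) -> None:
        sim_mode = self.simulation is not None
        load_mode = self.genotypes_path is not None
        if sim_mode == load_mode:
            raise ValueError(
                "exactly one of simulation / input paths must be given"
            )
        self.outdir = Path(self.outdir)


def _strata_from_series(s: pd.Series) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for acc, label in s.items():
        if label is None or (isinstance(label, float) and np.isnan(label)):
            continue
        out.setdefault(str(label), []).append(acc)
    return out


class PipelineRun:
    """Executes the stages and accumulates the report bundle."""

    def __init__(self, cfg: PipelineConfig) -> None:
        self.cfg = cfg
        self.outdir = cfg.outdir
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "seed": cfg.seed,
            "version": __version__,
            "stages": {},
        }
        self.genotypes: GenotypeMatrix | None = None
        self.traits: TraitMatrix | None = None
        self.metadata = None

    # -- helpers ----------------------------------------------------------
    def _record(self, stage: str, t0: float) -> None:
        self.manifest["stages"][stage] = {
            "seed": stage_seed(self.cfg.seed, stage),
            "wall_time_s": round(time.time() - t0, 3),
        }
        self._write_manifest()

    def _write_manifest(self) -> None:
        with open(self.outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)

    def _save(self, df: pd.DataFrame, name: str, **kw) -> None:
        df.to_csv(self.outdir / name, **kw)

    # -- stages -----------------------------------------------------------
    def load_inputs(self) -> None:
        t0 = time.time()
        cfg = self.cfg
        if cfg.simulation is not None:
            panel = simulate_panel(cfg.simulation)
            panel.write(self.outdir / "inputs")
            self.genotypes = panel.genotypes
            self.traits = panel.traits
            self.metadata = panel.metadata
            self.manifest["mode"] = "simulate"
            self.manifest["simulation_seed"] = cfg.simulation.seed
        else:
            self.genotypes = read_genotypes(
                cfg.genotypes_path, cfg.locus_info, drop_all_missing=True
            )
            self.traits = (
                read_traits(cfg.traits_path) if cfg.traits_path else None
            )
            self.metadata = (
                read_metadata(cfg.metadata_path) if cfg.metadata_path else None
            )
            self.manifest["mode"] = "load"
        self._record("inputs", t0)

    def marker_stage(self) -> None:
        t0 = time.time()
        g = self.genotypes
        self.mlgs = identify_mlgs(g)
        mlg_df = pd.DataFrame(
            {"accession": list(self.mlgs.mlg_of),
             "mlg": list(self.mlgs.mlg_of.values())}
        )
        self._save(mlg_df, "mlg.csv", index=False)
        acc_curve = genotype_accumulation(
            g, n_perm=self.cfg.accumulation_perm,
            seed=stage_seed(self.cfg.seed, "accumulation"),
        )
        self._save(acc_curve, "accumulation.csv")
        self.manifest["n_mlgs"] = self.mlgs.n_mlgs
        self.manifest["accumulation_saturated"] = acc_curve.attrs["saturated"]
        self._record("markers", t0)

    def structure_stage(self) -> None:
        t0 = time.time()
        g = self.genotypes
        reps = list(self.mlgs.representatives.values())
        g_reps = g.subset(reps)
        write_structure_format(g_reps, self.outdir / "structure_input.txt")
        model = AdmixtureModel(g_reps, self.cfg.sampler)
        battery = model.fit_battery(
            self.cfg.k_range, seed=stage_seed(self.cfg.seed, "structure")
        )
        self._save(battery.delta_k, "delta_k.csv")
        rep_assign = assign_membership(
            battery.best_run.q, self.cfg.membership_threshold
        )
        # propagate the representative's membership to its whole MLG
        rep_of = {m: r for m, r in self.mlgs.representatives.items()}
        rows = []
        for acc, m in self.mlgs.mlg_of.items():
            rep = rep_of[m]
            rows.append(
                {
                    "accession": acc,
                    "mlg": m,
                    "group": rep_assign.loc[rep, "group"],
                    "max_q": rep_assign.loc[rep, "max_q"],
                }
            )
        self.membership = pd.DataFrame(rows).set_index("accession")
        self._save(self.membership, "membership.csv")
        self._save(battery.best_run.q, "q_matrix.csv")
        self.battery = battery
        self.manifest["best_k"] = battery.best_k
        self._record("structure", t0)

    def _stratifications(self) -> dict[str, dict[str, list[str]]]:
        out = {"genetic_group": _strata_from_series(self.membership["group"])}
        out["genetic_group"].pop(ADMIXED, None)
        if self.metadata is not None:
            meta = metadata_frame(self.metadata)
            out["region"] = _strata_from_series(meta["region"])
            out["climate"] = _strata_from_series(meta["climate"])
        return out

    def diversity_stage(self) -> None:
        t0 = time.time()
        g = self.genotypes
        for name, strata in self._stratifications().items():
            if len(strata) < 2:
                continue
            table = stratum_diversity(g, strata)
            extra = pd.DataFrame(
                {"mean_fst": [table.attrs["mean_fst"]], "nm": [table.attrs["nm"]]}
            )
            self._save(table, f"stratum_stats_{name}.csv")
            self._save(extra, f"gene_flow_{name}.csv", index=False)
        per_locus = locus_indices(
            g, self._stratifications()["genetic_group"] or None
        )
        self._save(per_locus, "locus_stats.csv")
        self._record("diversity", t0)

    def distance_stage(self) -> None:
        t0 = time.time()
        g = self.genotypes
        groups = self._stratifications()["genetic_group"]
        if len(groups) >= 2:
            nei = nei_matrix(g, groups)
            self._save(nei.to_frame(), "nei_genetic_groups.csv")
        bruvo = bruvo_matrix(g)
        # MLG-level network: one node per MLG
        reps = list(self.mlgs.representatives.values())
        rep_b = bruvo.reorder(reps)
        rep_labels = {
            r: f"MLG{m}" for m, r in self.mlgs.representatives.items()
        }
        members = self.mlgs.members()
        msn = minimum_spanning_network(rep_b)
        attrs = {
            r: {
                "mlg": m,
                "n_accessions": len(members[m]),
                "group": self.membership.loc[r, "group"],
            }
            for m, r in self.mlgs.representatives.items()
        }
        edges, nodes = msn_tables(msn, attrs)
        self._save(edges, "msn_edges.csv", index=False)
        self._save(nodes, "msn_nodes.csv", index=False)
        self.bruvo = bruvo
        self._record("distances", t0)

    def amova_stage(self) -> None:
        t0 = time.time()
        d2 = genotypic_sq_matrix(self.genotypes)
        results = []
        for name, strata in self._stratifications().items():
            strata = {k: v for k, v in strata.items() if len(v) >= 1}
            if len(strata) < 2:
                continue
            res = amova_one_level(
                d2,
                strata,
                n_perm=self.cfg.n_perm,
                seed=stage_seed(self.cfg.seed, f"amova_{name}"),
                stratification=name,
            )
            results.append(res)
        self._save(amova_report(results), "amova.csv", index=False)
        self._record("amova", t0)

    def mantel_stage(self) -> None:
        t0 = time.time()
        rows = []
        if self.metadata is not None:
            geo = geographic_distance(self.metadata)
            gen = self.bruvo.reorder(geo.labels)
            r, p = mantel_test(
                gen, geo, n_perm=self.cfg.n_perm,
                seed=stage_seed(self.cfg.seed, "mantel_geo"),
            )
            rows.append({"pair": "genetic_vs_geographic", "r": r, "p": p})
        if self.traits is not None:
            td = trait_distance(self.traits)
            shared = [a for a in self.bruvo.labels if a in td.labels]
            r, p = mantel_test(
                self.bruvo.reorder(shared),
                td.reorder(shared),
                n_perm=self.cfg.n_perm,
                seed=stage_seed(self.cfg.seed, "mantel_trait"),
            )
            rows.append({"pair": "genetic_vs_trait", "r": r, "p": p})
        self._save(pd.DataFrame(rows), "mantel.csv", index=False)
        self._record("mantel", t0)

    def morpho_stage(self) -> None:
        t0 = time.time()
        if self.traits is None:
            return
        strata: dict[str, list[str]] = {}
        if self.metadata is not None:
            meta = metadata_frame(self.metadata)
            strata.update(_strata_from_series(meta["region"]))
            strata.update(_strata_from_series(meta["climate"]))
        table = diversity_table(self.traits, strata)
        self._save(table, "shannon_hprime.csv")
        memb = {
            acc: grp
            for acc, grp in self.membership["group"].items()
            if grp != ADMIXED and acc in self.traits.accession_ids
        }
        counts = pd.Series(memb).value_counts()
        memb = {a: g for a, g in memb.items() if counts[g] >= 2}
        if len(set(memb.values())) >= 2:
            means = cluster_trait_means(self.traits, memb)
            letters = compare_means(self.traits, memb)
            self._save(means, "cluster_trait_means.csv")
            self._save(letters, "cluster_trait_letters.csv")
        self._record("morpho", t0)

    def run(self) -> Path:
        for stage in (
            self.load_inputs,
            self.marker_stage,
            self.structure_stage,
            self.diversity_stage,
            self.distance_stage,
            self.amova_stage,
            self.mantel_stage,
            self.morpho_stage,
        ):
            try:
                stage()
            except Exception:
                self.manifest["failed_stage"] = stage.__name__
                self._write_manifest()
                logger.exception("pipeline stage %s failed", stage.__name__)
                raise
        self._write_manifest()
        return self.outdir


def load_inputs_from_dir(indir) -> tuple[GenotypeMatrix, TraitMatrix | None, list | None]:
    """Load the genotype/trait/metadata tables a previous run (or the
    simulator) wrote into *indir*."""
    from .io import LocusInfo

    indir = Path(indir)
    loci_df = pd.read_csv(indir / "loci.csv")
    loci = [
        LocusInfo(
            name=row["name"],
            chromosome=str(row.get("chromosome", "")),
            repeat_unit=int(row["repeat_unit"]),
        )
        for _, row in loci_df.iterrows()
    ]
    g = read_genotypes(indir / "genotypes.csv", loci, drop_all_missing=True)
    traits = (
        read_traits(indir / "traits.csv")
        if (indir / "traits.csv").exists()
        else None
    )
    meta = (
        read_metadata(indir / "metadata.csv")
        if (indir / "metadata.csv").exists()
        else None
    )
    return g, traits, meta


class CachedRun(PipelineRun):
    """A pipeline run that restores earlier stage outputs from the run
    directory, so individual stages can be re-run in isolation."""

    def load_inputs(self) -> None:
        inputs = self.outdir / "inputs"
        if self.cfg.simulation is not None and not (inputs / "genotypes.csv").exists():
            super().load_inputs()
            return
        t0 = time.time()
        src = inputs if (inputs / "genotypes.csv").exists() else None
        if src is not None:
            self.genotypes, self.traits, self.metadata = load_inputs_from_dir(src)
            self.manifest["mode"] = "cached"
            self._record("inputs", t0)
        else:
            super().load_inputs()

    def restore_markers(self) -> bool:
        path = self.outdir / "mlg.csv"
        if not path.exists():
            return False
        df = pd.read_csv(path)
        from .markers import MLGAssignment

        mlg_of = dict(zip(df["accession"].astype(str), df["mlg"].astype(int)))
        reps: dict[int, str] = {}
        for acc, m in mlg_of.items():
            reps.setdefault(m, acc)
        self.mlgs = MLGAssignment(mlg_of, reps)
        return True

    def restore_membership(self) -> bool:
        path = self.outdir / "membership.csv"
        if not path.exists():
            return False
        self.membership = pd.read_csv(path, index_col=0)
        return True

    def restore_bruvo(self) -> bool:
        self.bruvo = bruvo_matrix(self.genotypes)
        return True


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage; returns the output directory."""
    return PipelineRun(cfg).run()
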