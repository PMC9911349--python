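"""Stage orchestration with manifests and reproducible seeds.

Stages (in dependency order): simulate -> nc -> isor -> u1scan ->
classifier / mutation / popgen / coexpr.  Each stage reads its inputs from
the run directory, writes its outputs there, and records them (with SHA-256
hashes, parameters and the seed) in ``manifest.json``.  Re-running the same
configuration reproduces identical hashes for every deterministic stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from . import synthetic
from .coexpression import conservation_fraction, partner_sets
from .localization import nc_table
from .maxent import DONOR_CONSENSUS, MotifModel, scan_sequence, u1_density
from .mutation import count_alleles, test_export_shift, test_splice_shift
from .popgen import daf_spectrum, mc_skew_test
from .splicing import isor_table
from .synthetic import SimConfig


class DependencyError(RuntimeError):
    pass


STAGE_ORDER = ["simulate", "nc", "isor", "u1scan", "mutation", "popgen", "coexpr"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(outdir: Path, stage: str, *names: str) -> None:
    for name in names:
        if not (outdir / name).exists():
            raise DependencyError(f"stage {stage!r} needs missing input {name!r}")


def sample_donor_sites(rng: np.random.Generator, n: int = 300, mutation_rate: float = 0.15):
    """Noisy training sites around the donor consensus for the U1 model."""
    sites = []
    for _ in range(n):
        sites.append(synthetic._mutate_motif(rng, DONOR_CONSENSUS, mutation_rate))
    return sites


def default_u1_model(seed: int = 0, order: int = 2) -> MotifModel:
    rng = np.random.default_rng(seed)
    model = MotifModel.fit(sample_donor_sites(rng), constraint_order=order, pseudocount=1.0)
    model.calibrate_strong_threshold(rng)
    return model


def run(config: dict, outdir: str | Path) -> dict:
    """Execute the configured stages; returns (and writes) the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", STAGE_ORDER)
    seed = int(config.get("seed", 0))
    manifest: dict = {"seed": seed, "stages": {}}

    sim_params = dict(config.get("simulate", {}))
    sim_params.setdefault("seed", seed)
    sim_config = SimConfig(**sim_params)

    for stage in stages:
        outputs: list[str] = []
        if stage == "simulate":
            sequences, models, truth = synthetic.simulate_genome(sim_config)
            counts, junctions, fulllength = synthetic.simulate_fraction_counts(
                models, truth, sim_config
            )
            dio.write_fasta(sequences, outdir / "genome.fa")
            dio.write_gtf(models, outdir / "genes.gtf")
            counts.to_csv(outdir / "counts.tsv", sep="\t", index=False)
            junctions.to_csv(outdir / "junctions.tsv", sep="\t", index=False)
            fulllength.to_csv(outdir / "fulllength.tsv", sep="\t", index=False)
            truth.as_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
            outputs = [
                "genome.fa", "genes.gtf", "counts.tsv", "junctions.tsv",
                "fulllength.tsv", "truth.tsv",
            ]
        elif stage == "nc":
            _require(outdir, stage, "counts.tsv")
            counts = pd.read_csv(outdir / "counts.tsv", sep="\t")
            nc_table(counts).to_csv(outdir / "nc.tsv", sep="\t", index=False)
            outputs = ["nc.tsv"]
        elif stage == "isor":
            _require(outdir, stage, "junctions.tsv", "genes.gtf")
            models = dio.load_gene_models(outdir / "genes.gtf")
            junctions = pd.read_csv(outdir / "junctions.tsv", sep="\t")
            isor_table(models, junctions).to_csv(outdir / "isor.tsv", sep="\t", index=False)
            outputs = ["isor.tsv"]
        elif stage == "u1scan":
            _require(outdir, stage, "genome.fa", "genes.gtf")
            models = dio.load_gene_models(outdir / "genes.gtf")
            genome = dio.load_fasta(outdir / "genome.fa")
            model = default_u1_model(seed)
            model.to_json(outdir / "u1_model.json")
            rows = []
            for m in models:
                spliced = dio.get_spliced_sequence(m, genome)
                genic = dio.get_genic_sequence(m, genome)
                ex_hits, _ = scan_sequence(model, spliced, gene_id=m.gene_id)
                gen_hits, _ = scan_sequence(model, genic, gene_id=m.gene_id)
                rows.append(
                    {
                        "gene_id": m.gene_id,
                        "exonic_density": u1_density(ex_hits, m.exonic_length),
                        "genic_density": u1_density(gen_hits, m.genic_length),
                    }
                )
            pd.DataFrame(rows).to_csv(outdir / "u1_density.tsv", sep="\t", index=False)
            outputs = ["u1_model.json", "u1_density.tsv"]
        elif stage == "mutation":
            _require(outdir, stage, "genes.gtf")
            models = dio.load_gene_models(outdir / "genes.gtf")
            _, _, truth = synthetic.simulate_genome(sim_config)
            effects = []
            mut_cfg = config.get("mutation", {})
            multipliers = mut_cfg.get("odds_multipliers", [1.0, 4.0, 0.25])
            for i, m in enumerate(models[: mut_cfg.get("n_genes", 10)]):
                pos = m.span[0] + (m.span[1] - m.span[0]) // 2
                effects.append(
                    synthetic.InjectedEffect(
                        f"mut{i:04d}", m.gene_id, pos, "A", "G",
                        export_odds_multiplier=multipliers[i % len(multipliers)],
                        psi_delta=(-0.2 if i % 2 else 0.0),
                    )
                )
            reads, junct, _ = synthetic.simulate_mutation_assay(
                models, effects, sim_config, truth
            )
            counts, _ = count_alleles(reads)
            export = test_export_shift(counts)
            splice = test_splice_shift(junct)
            export.merge(splice, on="mutation_id", how="left").to_csv(
                outdir / "mutation_effects.tsv", sep="\t", index=False
            )
            outputs = ["mutation_effects.tsv"]
        elif stage == "popgen":
            sites = synthetic.simulate_population(sim_config)
            dio.write_vcf(sites, outdir / "population.vcf")
            classes = sorted({s.site_class for s in sites})
            freqs = {
                c: [s.derived_freq for s in sites if s.site_class == c] for c in classes
            }
            results = {}
            neutral = freqs.get("synonymous")
            for c in classes:
                spec = daf_spectrum(freqs[c], seed=seed)
                entry = {
                    "n_sites": spec.n_sites,
                    "proportions": spec.proportions.tolist(),
                    "bootstrap_sd": spec.bootstrap_sd.tolist(),
                }
                if neutral and c != "synonymous":
                    g1, p = mc_skew_test(freqs[c], neutral, seed=seed)
                    entry.update({"skewness": g1, "mc_p": p})
                results[c] = entry
            (outdir / "popgen.json").write_text(json.dumps(results, indent=2))
            outputs = ["population.vcf", "popgen.json"]
        elif stage == "coexpr":
            cfg = dataclasses.replace(
                sim_config,
                panel_blocks=config.get(
                    "coexpr_blocks",
                    [
                        {"n_genes": 10, "r": 0.8, "shared": True},
                        {"n_genes": 10, "r": 0.8, "shared": False},
                    ],
                ),
            )
            panel_a, panel_b, orthology = synthetic.simulate_expression_panel(cfg)
            orth = dict(zip(orthology["gene_a"], orthology["gene_b"]))
            focal = [g for g in panel_a.index if g.startswith("hsa_blk")][:10]
            rows = []
            for ps in partner_sets(panel_a, focal):
                frac, n_unmap = conservation_fraction(ps, panel_b, orth)
                rows.append(
                    {
                        "focal_gene": ps.focal_gene,
                        "n_partners": len(ps.partners),
                        "conservation_fraction": np.nan if frac is None else frac,
                        "n_unmappable": n_unmap,
                    }
                )
            pd.DataFrame(rows).to_csv(outdir / "conservation.tsv", sep="\t", index=False)
            outputs = ["conservation.tsv"]
        else:
            raise ValueError(f"unknown stage {stage!r}")
        manifest["stages"][stage] = {
            "outputs": {name: _sha256(outdir / name) for name in outputs},
            "params": config.get(stage, {}),
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
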