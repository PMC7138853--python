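"""Regenerate the packaged demo fixture (src/tmtquant/fixtures).

The fixture is a small synthetic cohort — 40 proteins, 3 TMT 10-plexes,
27 tissue samples — plus a companion synthetic single-plex mouse cohort's
differential-expression table, a homolog map, a gene-set collection and a
pipeline config.  Everything is produced by the package's own simulator;
run this script from the repository root after changing the generator.
"""

from pathlib import Path

from tmtquant import simulate as sim
from tmtquant.gsea import write_gmt
from tmtquant.quant import quantify_cohort
from tmtquant.stats import differential_expression, resolve_contrast

FIXTURE_DIR = Path(__file__).resolve().parents[1] / "src/tmtquant/fixtures"
SEED = 20200407

CONFIG_YAML = """\
# Demo pipeline configuration over the packaged synthetic cohort.
seed: 20200407
psm_tables: [psm_plex1.tsv, psm_plex2.tsv, psm_plex3.tsv]
design: design.tsv
annotation: annotation.tsv
gene_sets: genesets.gmt
homologs: homologs.tsv
mouse_de: mouse_de.tsv
rollup_by: gene
filter:
  min_peptide_probability: 0.9
  min_precursor_purity: 0.5
  min_ms1_intensity_percentile: 0.0005
  min_ms2_fraction: 0.05
impute: {m: 5, maxit: 50, donors: 5}
de_thresholds: {min_abs_log2fc: 1.0, max_p: 0.05, max_q: 0.1}
signature_thresholds: {max_p: 0.05, max_q: 0.1, min_log2fc: 1.0}
contrasts:
  - "tnbc+spindle+squamous+sarcomatoid:normal"
  - "spindle:tnbc"
signature_contrast: "tnbc+spindle+squamous+sarcomatoid:normal"
gsea: {n_perm: 1000, min_size: 5, max_size: 500, weight_exponent: 1}
cluster: {axis: samples, median_center: true}
"""


def main():
    FIXTURE_DIR.mkdir(parents=True, exist_ok=True)

    human_cfg = sim.CohortConfig(
        n_proteins=40, psms_per_protein=3.0, de_fraction=0.25,
        effect_size=1.5, seed=SEED,
    )
    human = sim.generate_cohort(human_cfg)
    sim.write_fixture(human, FIXTURE_DIR)

    # gene sets over the human universe (true-DE positives + random sets)
    sets = sim.make_gene_sets(human.truth.de_flags, n_random=12,
                              size_range=(5, 10), seed=SEED)
    write_gmt(sets, FIXTURE_DIR / "genesets.gmt")

    # companion synthetic mouse cohort: single plex, same planted DE genes
    de = human.truth.de_flags
    de_genes_h = list(de.index[de["is_de"]])
    mouse_genes = tuple(g[0] + g[1:].lower() for g in de_genes_h)
    mouse_cfg = sim.CohortConfig(
        n_plexes=1, n_proteins=40, psms_per_protein=3.0,
        group_sizes={"normal": 4, "spindle": 5}, de_mode="shared",
        de_genes=mouse_genes,
        de_signs=tuple(de.loc[de_genes_h, "sign"]),
        effect_size=1.5, missing_rates=(0.05,), gene_style="mouse",
        seed=SEED + 1,
    )
    mouse = sim.generate_cohort(mouse_cfg)
    mquant = quantify_cohort(mouse.psm_tables, mouse.designs)
    ga, gb = resolve_contrast(mouse.annotation, "spindle:normal")
    mouse_de = differential_expression(mquant.abundance, ga, gb)
    mouse_de.rename_axis("gene").to_csv(FIXTURE_DIR / "mouse_de.tsv",
                                        sep="\t", na_rep="")

    homologs = sim.make_homolog_map(
        [f"GENE{i + 1:04d}" for i in range(40)])
    homologs.to_csv(FIXTURE_DIR / "homologs.tsv", sep="\t", index=False)

    (FIXTURE_DIR / "config.yaml").write_text(CONFIG_YAML)
    sizes = {p.name: p.stat().st_size for p in sorted(FIXTURE_DIR.iterdir())}
    total = sum(sizes.values())
    for name, size in sizes.items():
        print(f"{size:>8d}  {name}")
    print(f"{total:>8d}  TOTAL")


if __name__ == "__main__":
    main()
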