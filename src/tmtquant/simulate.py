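"""Synthetic multi-plex TMT PSM-level cohorts with known ground truth.

Emulates the raw material of an isobaric-labeling experiment: several TMT
10-plex runs, each carrying nine tissue samples plus one pooled ("master
mix") reference channel, measured at the level of peptide-spectrum matches
(PSMs).  Every generated cohort comes with the ground truth needed to score
the downstream pipeline: the true protein log2 abundances, which proteins
carry group effects, the per-plex batch offsets, the reporter cells that
were blanked, and which PSMs were deliberately corrupted.

Reporter intensities are generated multiplicatively on the log2 scale::

    reporter = 2 ** (true_abundance + batch_shift + psm_effect + noise)

where ``psm_effect`` is a per-PSM ionization-efficiency offset shared by all
ten channels of the PSM (it cancels in ratio space) and ``noise`` is i.i.d.
per reporter cell.  The reference channel carries the linear mean of all
cohort samples' true signal (the master-mix construction) times the same
per-PSM effect; batch shifts are applied to sample channels only, so per-plex
offsets survive into ratio-to-reference space where the batch-correction
stage must remove them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

TMT10_CHANNELS = [
    "126", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C", "131",
]
REPORTER_COLUMNS = [f"channel_{c}" for c in TMT10_CHANNELS]
REFERENCE_CHANNEL = "channel_131"
PSM_COLUMNS = [
    "spectrum_id", "peptide", "protein", "gene", "is_unique",
    "peptide_probability", "precursor_purity", "ms1_intensity",
    "ms2_summed_intensity", *REPORTER_COLUMNS,
]
#: hidden-truth column marking deliberately corrupted PSMs ("" = clean)
QC_COLUMN = "qc_violation"
CONTAMINANT_PREFIX = "contam_"
VIOLATION_KINDS = ("probability", "purity", "reference_missing", "ms1_low", "ms2_low")

DEFAULT_GROUP_SIZES = {
    "normal": 6, "tnbc": 6, "spindle": 6, "squamous": 4, "sarcomatoid": 5,
}

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class CohortConfig:
    """Study design and noise model for one synthetic cohort.

    Defaults reproduce the study conditions this package targets: three
    TMT 10-plexes carrying 27 tissue samples (normal, TNBC and three
    metaplastic-carcinoma subtypes) plus one pooled reference per plex,
    with per-plex missingness of 18%, 14% and 12%.
    """

    n_plexes: int = 3
    channels_per_plex: int = 10
    n_proteins: int = 300
    psms_per_protein: float = 4.0
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    control_group: str = "normal"
    de_fraction: float = 0.10
    effect_size: float = 1.5
    de_mode: str = "shared"        # "shared": effect in every non-control group;
                                   # "subtype": effect in one random non-control group
    de_genes: tuple | None = None  # explicit DE gene symbols (overrides random draw)
    de_signs: tuple | None = None  # signs matching de_genes
    bio_sd: float = 0.2            # between-sample biological variation, log2 units
    psm_noise_sd: float = 0.3      # per reporter cell, log2 units
    psm_effect_sd: float = 0.4     # per-PSM ionization offset, log2 units
    batch_shift_sd: float = 0.3    # per plex x protein, log2 units
    baseline_mean: float = 25.0    # log2 of a typical reporter intensity
    baseline_sd: float = 1.0
    missing_rates: tuple = (0.18, 0.14, 0.12)
    missing_mechanism: str = "mnar"  # "mnar" (intensity-dependent) or "mcar"
    mnar_scale: float = 1.0
    contaminant_fraction: float = 0.02
    lowquality_fraction: float = 0.05
    gene_style: str = "human"      # "human" -> GENE0001, "mouse" -> Gene0001
    seed: int = 0

    def validate(self) -> None:
        if self.channels_per_plex != 10:
            raise ValueError("channels_per_plex: the TMT 10-plex schema is fixed at 10")
        n_sample_channels = self.n_plexes * (self.channels_per_plex - 1)
        if sum(self.group_sizes.values()) != n_sample_channels:
            raise ValueError(
                "group_sizes: sum must equal n_plexes * (channels_per_plex - 1) "
                f"= {n_sample_channels}, got {sum(self.group_sizes.values())}"
            )
        if self.control_group not in self.group_sizes:
            raise ValueError("control_group: not among group_sizes labels")
        for name in ("de_fraction", "contaminant_fraction", "lowquality_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}: must be in [0, 1], got {v}")
        for name in ("bio_sd", "psm_noise_sd", "psm_effect_sd", "batch_shift_sd",
                     "baseline_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name}: must be >= 0")
        if len(self.missing_rates) != self.n_plexes:
            raise ValueError("missing_rates: need one rate per plex")
        for r in self.missing_rates:
            if not 0.0 <= r < 0.9:
                raise ValueError(f"missing_rates: each rate must be in [0, 0.9), got {r}")
        if self.psms_per_protein < 1:
            raise ValueError("psms_per_protein: must be >= 1")
        if self.de_mode not in ("shared", "subtype"):
            raise ValueError("de_mode: must be 'shared' or 'subtype'")
        if self.missing_mechanism not in ("mnar", "mcar"):
            raise ValueError("missing_mechanism: must be 'mnar' or 'mcar'")
        if (self.de_signs is None) != (self.de_genes is None):
            raise ValueError("de_genes: de_genes and de_signs must be given together")


@dataclass
class GroundTruth:
    """Everything needed to score the pipeline against the simulation."""

    protein_abundance: pd.DataFrame   # genes x tissue samples, true log2 abundance
    de_flags: pd.DataFrame            # per gene: is_de, sign, effect, affected_groups
    batch_shifts: pd.DataFrame        # genes x plex ids
    missing_masks: list               # per plex: PSM rows x reporter columns, bool


@dataclass
class CohortBundle:
    psm_tables: list        # one DataFrame per plex, PSM_COLUMNS (+ QC_COLUMN)
    designs: list           # one DataFrame per plex: plex_id, channel, sample_id, is_reference
    annotation: pd.DataFrame  # sample_id, group, batch
    truth: GroundTruth


def _gene_symbols(n: int, style: str) -> list:
    if style == "mouse":
        return [f"Gene{i + 1:04d}" for i in range(n)]
    return [f"GENE{i + 1:04d}" for i in range(n)]


def _random_peptides(rng: np.random.Generator, n: int) -> list:
    lengths = rng.integers(8, 16, size=n)
    letters = rng.integers(0, len(_AMINO_ACIDS), size=(n, 15))
    return ["".join(_AMINO_ACIDS[row[:ln]]) for row, ln in zip(letters, lengths)]


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate PSM tables, plex designs, sample annotation and ground truth.

    Deterministic: the same config (including seed) yields identical output.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_truth, rng_psm, rng_contam, rng_lowq, rng_miss = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    # --- samples, plex assignment, annotation -------------------------------
    samples, groups = [], []
    for g, size in config.group_sizes.items():
        for i in range(size):
            samples.append(f"{g}_{i + 1:02d}")
            groups.append(g)
    plex_ids = [f"plex{k + 1}" for k in range(config.n_plexes)]
    plex_of = {s: plex_ids[i % config.n_plexes] for i, s in enumerate(samples)}
    annotation = pd.DataFrame(
        {"sample_id": samples, "group": groups,
         "batch": [plex_of[s] for s in samples]}
    )

    designs = []
    plex_samples: dict = {p: [] for p in plex_ids}
    for s in samples:
        plex_samples[plex_of[s]].append(s)
    for p in plex_ids:
        chan_samples = plex_samples[p]
        rows = [
            {"plex_id": p, "channel": REPORTER_COLUMNS[i], "sample_id": s,
             "is_reference": False}
            for i, s in enumerate(chan_samples)
        ]
        rows.append({"plex_id": p, "channel": REFERENCE_CHANNEL,
                     "sample_id": f"ref_{p}", "is_reference": True})
        designs.append(pd.DataFrame(rows))

    # --- ground truth -------------------------------------------------------
    genes = _gene_symbols(config.n_proteins, config.gene_style)
    baseline = rng_truth.normal(config.baseline_mean, config.baseline_sd,
                                config.n_proteins)
    if config.de_genes is not None:
        unknown = set(config.de_genes) - set(genes)
        if unknown:
            raise ValueError(f"de_genes: not in gene universe: {sorted(unknown)}")
        de_idx = np.array([genes.index(g) for g in config.de_genes], dtype=int)
        signs_de = np.asarray(config.de_signs, dtype=float)
    else:
        n_de = int(round(config.de_fraction * config.n_proteins))
        de_idx = rng_truth.choice(config.n_proteins, size=n_de, replace=False)
        signs_de = rng_truth.choice([-1.0, 1.0], size=n_de)
    tumor_groups = [g for g in config.group_sizes if g != config.control_group]
    affected: dict = {}
    signs = np.zeros(config.n_proteins)
    signs[de_idx] = signs_de
    for j, gi in enumerate(de_idx):
        if config.de_mode == "shared":
            affected[gi] = tuple(tumor_groups)
        else:
            affected[gi] = (tumor_groups[rng_truth.integers(len(tumor_groups))],)

    effect = np.zeros((config.n_proteins, len(samples)))
    for gi, grps in affected.items():
        for j, s in enumerate(samples):
            if groups[j] in grps:
                effect[gi, j] = signs[gi] * config.effect_size
    bio = rng_truth.normal(0.0, config.bio_sd, (config.n_proteins, len(samples)))
    abundance = baseline[:, None] + effect + bio
    protein_abundance = pd.DataFrame(
        abundance, index=pd.Index(genes, name="gene"), columns=samples)

    de_flags = pd.DataFrame(
        {
            "is_de": [i in affected for i in range(config.n_proteins)],
            "sign": signs,
            "effect": signs * config.effect_size,
            "affected_groups": [
                ";".join(affected.get(i, ())) for i in range(config.n_proteins)
            ],
        },
        index=pd.Index(genes, name="gene"),
    )
    batch_shifts = pd.DataFrame(
        rng_truth.normal(0.0, config.batch_shift_sd,
                         (config.n_proteins, config.n_plexes)),
        index=pd.Index(genes, name="gene"), columns=plex_ids,
    )

    # master mix: linear mean of all cohort samples' true signal, per protein
    mm_log2 = np.log2(np.mean(2.0 ** abundance, axis=1))

    # --- PSM tables per plex ------------------------------------------------
    psm_tables = []
    for k, p in enumerate(plex_ids):
        cols = plex_samples[p]
        col_idx = [samples.index(s) for s in cols]
        counts = 1 + rng_psm.poisson(max(config.psms_per_protein - 1.0, 0.0),
                                     config.n_proteins)
        prot_idx = np.repeat(np.arange(config.n_proteins), counts)
        n_rows = len(prot_idx)

        psm_eff = rng_psm.normal(0.0, config.psm_effect_sd, n_rows)
        noise = rng_psm.normal(0.0, config.psm_noise_sd, (n_rows, 10))
        log2_samp = (abundance[np.ix_(prot_idx, col_idx)]
                     + batch_shifts.values[prot_idx, k][:, None]
                     + psm_eff[:, None] + noise[:, :9])
        log2_ref = mm_log2[prot_idx] + psm_eff + noise[:, 9]
        reporters = np.empty((n_rows, 10))
        reporters[:, :9] = 2.0 ** log2_samp
        reporters[:, 9] = 2.0 ** log2_ref

        prob = 1.0 - 0.1 * rng_psm.random(n_rows) ** 2
        purity = 0.5 + 0.5 * np.sqrt(rng_psm.random(n_rows))
        is_unique = rng_psm.random(n_rows) < 0.85
        ms1 = reporters.sum(axis=1) * 2.0 ** rng_psm.normal(0.0, 0.3, n_rows)
        table = pd.DataFrame(reporters, columns=REPORTER_COLUMNS)
        table.insert(0, "peptide", _random_peptides(rng_psm, n_rows))
        table.insert(1, "protein", [f"PROT{i + 1:04d}" for i in prot_idx])
        table.insert(2, "gene", [genes[i] for i in prot_idx])
        table.insert(3, "is_unique", is_unique)
        table.insert(4, "peptide_probability", prob)
        table.insert(5, "precursor_purity", purity)
        table.insert(6, "ms1_intensity", ms1)

        # contaminants: protein IDs with the conventional prefix
        n_cont = int(round(config.contaminant_fraction * n_rows))
        if n_cont:
            base_c = rng_contam.normal(config.baseline_mean, config.baseline_sd,
                                       n_cont)
            rep_c = 2.0 ** (base_c[:, None]
                            + rng_contam.normal(0.0, config.psm_noise_sd,
                                                (n_cont, 10)))
            which = rng_contam.integers(1, 6, n_cont)
            cont = pd.DataFrame(rep_c, columns=REPORTER_COLUMNS)
            cont.insert(0, "peptide", _random_peptides(rng_contam, n_cont))
            cont.insert(1, "protein",
                        [f"{CONTAMINANT_PREFIX}CONT{w:03d}" for w in which])
            cont.insert(2, "gene",
                        [f"{CONTAMINANT_PREFIX}CONT{w:03d}" for w in which])
            cont.insert(3, "is_unique", True)
            cont.insert(4, "peptide_probability",
                        1.0 - 0.1 * rng_contam.random(n_cont) ** 2)
            cont.insert(5, "precursor_purity",
                        0.5 + 0.5 * np.sqrt(rng_contam.random(n_cont)))
            cont.insert(6, "ms1_intensity",
                        rep_c.sum(axis=1)
                        * 2.0 ** rng_contam.normal(0.0, 0.3, n_cont))
            table = pd.concat([table, cont], ignore_index=True)

        # floor dim rows so that clean PSMs always clear the intensity filters
        # (raising values strictly below the max / median leaves those
        # reference statistics unchanged)
        rep = table[REPORTER_COLUMNS].values
        ms1v = table["ms1_intensity"].values.copy()
        ms1_floor = 1e-3 * ms1v.max()
        ms1v[ms1v < ms1_floor] = ms1_floor
        table["ms1_intensity"] = ms1v
        sums = rep.sum(axis=1)
        ms2_floor = 0.1 * np.median(sums)
        low = sums < ms2_floor
        if low.any():
            rep[low] *= (ms2_floor / sums[low])[:, None]
            table.loc[:, REPORTER_COLUMNS] = rep

        order = rng_psm.permutation(len(table))
        table = table.iloc[order].reset_index(drop=True)
        table.insert(0, "spectrum_id",
                     [f"{p}.{i + 1:06d}" for i in range(len(table))])
        table["ms2_summed_intensity"] = table[REPORTER_COLUMNS].sum(axis=1)
        table = table[PSM_COLUMNS]
        table[QC_COLUMN] = ""
        table.loc[table["protein"].str.startswith(CONTAMINANT_PREFIX),
                  QC_COLUMN] = "contaminant"
        psm_tables.append(table)

    psm_tables = [
        inject_low_quality(t, config.lowquality_fraction,
                           seed=np.random.SeedSequence([config.seed, 101, k]))
        for k, t in enumerate(psm_tables)
    ]
    psm_tables, masks = inject_missingness(
        psm_tables, config.missing_rates,
        seed=np.random.SeedSequence([config.seed, 202]),
        mechanism=config.missing_mechanism, scale=config.mnar_scale,
    )

    truth = GroundTruth(protein_abundance, de_flags, batch_shifts, masks)
    return CohortBundle(psm_tables, designs, annotation, truth)


def inject_low_quality(psms: pd.DataFrame, lowquality_fraction: float,
                       seed=0, reference_channel: str = REFERENCE_CHANNEL
                       ) -> pd.DataFrame:
    """Corrupt ``round(fraction * n)`` PSMs so each violates one filter criterion.

    The violated criterion is recorded in the hidden ``qc_violation`` column,
    giving downstream filter tests an exact expected answer.  Rows already
    labeled (e.g. contaminants) are never chosen.
    """
    if not 0.0 <= lowquality_fraction <= 1.0:
        raise ValueError("lowquality_fraction: must be in [0, 1]")
    out = psms.copy()
    if QC_COLUMN not in out.columns:
        out[QC_COLUMN] = ""
    n_alter = int(round(lowquality_fraction * len(out)))
    if n_alter == 0:
        return out
    rng = np.random.default_rng(seed)
    clean_pos = np.flatnonzero((out[QC_COLUMN] == "").values)
    if n_alter > len(clean_pos):
        warnings.warn("fewer clean PSMs than requested alterations; clamping")
        n_alter = len(clean_pos)
    chosen = rng.choice(clean_pos, size=n_alter, replace=False)
    kinds = rng.choice(VIOLATION_KINDS, size=n_alter)

    untouched = np.ones(len(out), bool)
    untouched[chosen] = False
    ms1_ref = out["ms1_intensity"].values[untouched].max()
    ms2_ref = np.median(out["ms2_summed_intensity"].values[untouched])

    cols = {c: out.columns.get_loc(c) for c in out.columns}
    for pos, kind in zip(chosen, kinds):
        if kind == "probability":
            out.iat[pos, cols["peptide_probability"]] = rng.uniform(0.3, 0.89)
        elif kind == "purity":
            out.iat[pos, cols["precursor_purity"]] = rng.uniform(0.05, 0.49)
        elif kind == "reference_missing":
            out.iat[pos, cols[reference_channel]] = np.nan
            rep = out.iloc[pos][REPORTER_COLUMNS].astype(float)
            out.iat[pos, cols["ms2_summed_intensity"]] = np.nansum(rep.values)
        elif kind == "ms1_low":
            out.iat[pos, cols["ms1_intensity"]] = 1e-4 * ms1_ref
        elif kind == "ms2_low":
            cur = out.iat[pos, cols["ms2_summed_intensity"]]
            factor = (1e-3 * ms2_ref) / cur
            for rc in REPORTER_COLUMNS:
                out.iat[pos, cols[rc]] = out.iat[pos, cols[rc]] * factor
            out.iat[pos, cols["ms2_summed_intensity"]] = cur * factor
        out.iat[pos, cols[QC_COLUMN]] = kind
    return out


def inject_missingness(psm_tables: list, missing_rates, seed=0,
                       mechanism: str = "mnar", scale: float = 1.0,
                       reference_channel: str = REFERENCE_CHANNEL):
    """Blank reporter cells; returns ``(tables, masks)``.

    The number blanked per plex is exactly ``round(rate * n_cells)`` over the
    non-reference reporter cells, so the realized rate is always within
    rounding of the request.  Under ``mnar`` the blanking probability is a
    logistic function of cell intensity (low-abundance cells preferred);
    ``mcar`` blanks uniformly.  The reference channel is never blanked.
    """
    if len(missing_rates) != len(psm_tables):
        raise ValueError("missing_rates: need one rate per plex")
    for r in missing_rates:
        if r >= 0.9:
            raise ValueError("missing rate >= 0.9 leaves roll-up undefined")
        if r < 0:
            raise ValueError("missing rate must be >= 0")
    rng = np.random.default_rng(seed)
    sample_cols = [c for c in REPORTER_COLUMNS if c != reference_channel]
    out_tables, masks = [], []
    for table, rate in zip(psm_tables, missing_rates):
        out = table.copy()
        mask = pd.DataFrame(False, index=out.index, columns=REPORTER_COLUMNS)
        vals = out[sample_cols].values
        present = np.isfinite(vals)
        n_cells = int(present.sum())
        n_miss = int(round(rate * n_cells))
        if n_miss > 0:
            flat = np.flatnonzero(present.ravel())
            if mechanism == "mnar":
                x = np.log2(vals.ravel()[flat])
                z = (x - np.median(x)) / scale
                logw = -np.logaddexp(0.0, z)     # log sigmoid(-(x - c)/s)
                keys = logw + rng.gumbel(size=len(flat))
            else:
                keys = rng.random(len(flat))
            top = flat[np.argpartition(-keys, n_miss - 1)[:n_miss]]
            hit = np.zeros(vals.size, bool)
            hit[top] = True
            hit = hit.reshape(vals.shape)
            vals = vals.copy()
            vals[hit] = np.nan
            out.loc[:, sample_cols] = vals
            mask.loc[:, sample_cols] = hit
        out_tables.append(out)
        masks.append(mask)
    return out_tables, masks


# --- fixture I/O -----------------------------------------------------------

def write_fixture(bundle: CohortBundle, directory) -> dict:
    """Write a cohort as plain TSV files; round-trip with :func:`read_fixture`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _write(name, df, index=False):
        p = directory / name
        df.to_csv(p, sep="\t", index=index, na_rep="")
        paths[name] = p

    qc_frames = []
    for k, table in enumerate(bundle.psm_tables):
        _write(f"psm_plex{k + 1}.tsv", table[PSM_COLUMNS])
        if QC_COLUMN in table.columns:
            qc = table[["spectrum_id", QC_COLUMN]].copy()
            qc.insert(0, "plex_id", f"plex{k + 1}")
            qc_frames.append(qc)
        _write(f"truth_missing_plex{k + 1}.tsv",
               bundle.truth.missing_masks[k].astype(int))
    _write("design.tsv", pd.concat(bundle.designs, ignore_index=True))
    _write("annotation.tsv", bundle.annotation)
    if qc_frames:
        _write("truth_qc.tsv", pd.concat(qc_frames, ignore_index=True))
    ab = bundle.truth.protein_abundance.copy()
    ab.index.name = "gene"
    _write("truth_abundance.tsv", ab, index=True)
    _write("truth_de.tsv", bundle.truth.de_flags, index=True)
    bs = bundle.truth.batch_shifts.copy()
    bs.index.name = "gene"
    _write("truth_batch_shifts.tsv", bs, index=True)
    return paths


def read_fixture(directory) -> CohortBundle:
    """Read a cohort previously written by :func:`write_fixture`."""
    directory = Path(directory)
    design = pd.read_csv(directory / "design.tsv", sep="\t")
    plex_ids = list(design["plex_id"].unique())
    designs = [design[design["plex_id"] == p].reset_index(drop=True)
               for p in plex_ids]
    annotation = pd.read_csv(directory / "annotation.tsv", sep="\t")
    qc_path = directory / "truth_qc.tsv"
    qc = pd.read_csv(qc_path, sep="\t").fillna({QC_COLUMN: ""}) \
        if qc_path.exists() else None

    psm_tables, masks = [], []
    for k, p in enumerate(plex_ids):
        table = pd.read_csv(directory / f"psm_plex{k + 1}.tsv", sep="\t")
        if qc is not None:
            sub = qc[qc["plex_id"] == p][["spectrum_id", QC_COLUMN]]
            table = table.merge(sub, on="spectrum_id", how="left")
            table[QC_COLUMN] = table[QC_COLUMN].fillna("")
        psm_tables.append(table)
        mpath = directory / f"truth_missing_plex{k + 1}.tsv"
        if mpath.exists():
            masks.append(pd.read_csv(mpath, sep="\t").astype(bool))
    abundance = pd.read_csv(directory / "truth_abundance.tsv", sep="\t",
                            index_col="gene")
    de = pd.read_csv(directory / "truth_de.tsv", sep="\t", index_col="gene")
    de["affected_groups"] = de["affected_groups"].fillna("")
    shifts = pd.read_csv(directory / "truth_batch_shifts.tsv", sep="\t",
                         index_col="gene")
    truth = GroundTruth(abundance, de, shifts, masks)
    return CohortBundle(psm_tables, designs, annotation, truth)


# --- companion fixtures -----------------------------------------------------

def make_gene_sets(de_flags: pd.DataFrame, n_random: int = 20,
                   size_range=(5, 15), seed: int = 0) -> dict:
    """Build a gene-set collection over the synthetic universe.

    Two sets collect the truly up- and downregulated genes (positive
    controls for enrichment); the rest are random draws from the universe.
    """
    rng = np.random.default_rng(seed)
    universe = list(de_flags.index)
    sets = {}
    up = list(de_flags.index[(de_flags["is_de"]) & (de_flags["sign"] > 0)])
    down = list(de_flags.index[(de_flags["is_de"]) & (de_flags["sign"] < 0)])
    if len(up) >= size_range[0]:
        sets["TRUE_UP"] = up
    if len(down) >= size_range[0]:
        sets["TRUE_DOWN"] = down
    for i in range(n_random):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        members = rng.choice(universe, size=size, replace=False)
        sets[f"RANDOM_{i + 1:03d}"] = sorted(members)
    return sets


def make_homolog_map(genes) -> pd.DataFrame:
    """Mouse-style (title-case) to human-style (upper-case) symbol map."""
    src = [g[0].upper() + g[1:].lower() for g in genes]
    return pd.DataFrame({"source": src, "target": [g.upper() for g in genes]})
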