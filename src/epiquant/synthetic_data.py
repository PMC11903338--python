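"""Synthetic epimicrobiota fixtures with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: the full sampling design (7 algal tissues x 10 months x
triplicates with two 2-replicate deficits, plus negative controls), true
total surface loads spanning the observed range (~1e5 to 5e7 copies cm^-2,
drawn log-normally), and taxa planted in distinct ecological roles:

* core genera        — present in every sample on every tissue;
* host-specific      — positive abundance only on samples of one host;
* seasonal           — abundance multiplied by a fold factor in one season;
* background         — sparse, occurring in a random subset of samples;
* organellar         — chloroplast-like lineages the pipeline must filter;
* contaminant        — dominant in negative controls, sparse and rare in
                       real samples (within the contaminant-filter bounds).

Reads are multinomial draws from each sample's true composition; qPCR
measurements add log-normal noise to the true load and are emitted as
copies-in-reaction so the surface-density formula is exercised end to end.
All randomness flows from a single integer seed.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from epiquant.io_model import (
    DEFAULT_DEFICITS,
    RANKS,
    SAMPLED_MONTHS,
    SEASON_MAP,
    TISSUES,
    TISSUE_TO_HOST,
    AsvTable,
    SampleMetadata,
    TaxonomyTable,
    enumerate_design,
)
from epiquant.qpcr_quant import DEFAULT_C_IN, DEFAULT_SURFACE, DEFAULT_V, DEFAULT_V_IN


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; defaults mirror the target study's shape."""

    tissues: tuple[str, ...] = TISSUES
    months: tuple[str, ...] = SAMPLED_MONTHS
    replicates: int = 3
    deficits: tuple[tuple[str, str, int], ...] = DEFAULT_DEFICITS
    n_controls: int = 2

    n_core: int = 10                  # planted core genera (2 ASVs each)
    n_host_specific_per_host: int = 2
    n_seasonal: int = 6
    n_background: int = 120
    n_organellar: int = 3
    n_contaminants: int = 10

    load_log10_mean: float = 6.85     # year-round average ~7e6 copies/cm^2
    load_log10_sd: float = 0.4
    load_clamp: tuple[float, float] = (1e5, 5e7)

    seasonal_fold: float = 8.0        # abundance multiplier in the taxon's season
    seasonal_offseason_occurrence: float = 0.35  # detection rate off-season
    background_occurrence: float = 0.15
    replicate_noise_sd: float = 0.5   # log-scale sd of per-sample weight noise
    dropout: float = 0.0              # probability of zeroing a taxon in a sample

    contaminant_freq: int = 5         # real samples carrying each contaminant
    contaminant_relab: float = 0.005  # its approximate relative abundance there

    depth: int = 20000                # reads per sample
    qpcr_cv: float = 0.2              # log-scale sd of qPCR measurement noise

    def validate(self) -> None:
        if self.n_core + self.n_background + self.n_seasonal <= 0:
            raise ValueError("infeasible config: no taxa to generate")
        if self.dropout < 0 or self.dropout >= 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.qpcr_cv < 0:
            raise ValueError("qpcr_cv must be >= 0")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


@dataclasses.dataclass
class SyntheticTruth:
    """Planted parameters and per-sample ground truth."""

    config: SyntheticConfig
    seed: int
    metadata: SampleMetadata
    taxonomy: TaxonomyTable
    roles: pd.Series                 # asv_id -> role string
    true_loads: pd.Series            # real samples, copies cm^-2
    true_relab: pd.DataFrame         # all samples x all ASVs; rows sum to 1
    true_absolute: pd.DataFrame      # real samples x retained ASVs, copies cm^-2
    core_genera: list[str]
    host_specific: dict[str, str]    # genus -> host
    seasonal: dict[str, tuple[str, float]]  # genus -> (season, fold)
    contaminant_asvs: list[str]

    @property
    def real_ids(self) -> list[str]:
        return self.metadata.real_ids

    def genus_of(self, asv_id: str) -> str:
        return self.taxonomy.lineages.loc[asv_id, "genus"]


def _lineage(genus: str, phylum: str = "Pseudomonadota", cls: str = "Gammaproteobacteria") -> dict:
    return {
        "domain": "Bacteria",
        "phylum": phylum,
        "class": cls,
        "order": f"{genus}ales",
        "family": f"{genus}aceae",
        "genus": genus,
        "species": "",
    }


def generate_truth(config: SyntheticConfig | None = None, seed: int = 0) -> SyntheticTruth:
    """Draw a full synthetic study with planted roles; deterministic per seed."""
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    design = enumerate_design(config.tissues, config.months, config.replicates,
                              config.deficits)
    real_ids = design["sample_id"].tolist()
    control_ids = [f"NegCtrl-{i + 1}" for i in range(config.n_controls)]

    # --- metadata ----------------------------------------------------------
    dna = 10.0 ** np.clip(rng.normal(0.85, 0.45, len(real_ids)), np.log10(0.11),
                          np.log10(41.5))
    meta = pd.DataFrame(
        {
            "tissue": design["tissue"].to_numpy(),
            "month": design["month"].to_numpy(),
            "replicate": design["replicate"].to_numpy(),
            "dna_conc": dna,
            "is_negative_control": False,
        },
        index=pd.Index(real_ids, name="sample_id"),
    )
    ctrl = pd.DataFrame(
        {
            "tissue": "",
            "month": "",
            "replicate": 0,
            "dna_conc": 0.2,
            "is_negative_control": True,
        },
        index=pd.Index(control_ids, name="sample_id"),
    )
    metadata = SampleMetadata(pd.concat([meta, ctrl]))
    hosts = tuple(dict.fromkeys(TISSUE_TO_HOST[t] for t in config.tissues))
    seasons = tuple(dict.fromkeys(SEASON_MAP[m] for m in config.months))

    # --- taxa, roles, taxonomy --------------------------------------------
    asv_rows: list[tuple[str, str, dict]] = []  # (asv_id, role, lineage)
    core_genera, host_specific, seasonal = [], {}, {}

    def add(role: str, lineage: dict) -> str:
        asv_id = f"ASV{len(asv_rows) + 1:04d}"
        asv_rows.append((asv_id, role, lineage))
        return asv_id

    for i in range(config.n_core):
        genus = f"Core{i + 1:02d}"
        core_genera.append(genus)
        for _ in range(2):  # two ASVs per core genus exercises genus pooling
            add("core", _lineage(genus))
    for host in hosts:
        for j in range(config.n_host_specific_per_host):
            genus = f"{host}Spec{j + 1}"
            host_specific[genus] = host
            add(f"host:{host}", _lineage(genus, phylum="Bacteroidota", cls="Bacteroidia"))
    for i in range(config.n_seasonal):
        season = seasons[i % len(seasons)]
        genus = f"Seas{season.capitalize()}{i + 1}"
        seasonal[genus] = (season, config.seasonal_fold)
        add(f"season:{season}", _lineage(genus, phylum="Planctomycetota",
                                         cls="Planctomycetes"))
    for i in range(config.n_background):
        add("background", _lineage(f"Bkg{i + 1:03d}", phylum="Actinomycetota",
                                   cls="Acidimicrobiia"))
    for i in range(config.n_organellar):
        lin = _lineage(f"Chloro{i + 1}", phylum="Cyanobacteria", cls="Cyanobacteriia")
        lin["order"] = "Chloroplast"
        add("organellar", lin)
    contaminant_asvs = []
    for i in range(config.n_contaminants):
        asv_id = add("contaminant", _lineage(f"Contam{i + 1:02d}",
                                             phylum="Pseudomonadota",
                                             cls="Alphaproteobacteria"))
        contaminant_asvs.append(asv_id)

    asv_ids = [r[0] for r in asv_rows]
    roles = pd.Series({r[0]: r[1] for r in asv_rows}, name="role")
    taxonomy = TaxonomyTable(
        pd.DataFrame([r[2] for r in asv_rows], index=pd.Index(asv_ids, name="asv_id"))
        [list(RANKS)]
    )

    # --- per-sample composition weights ------------------------------------
    n_real, n_taxa = len(real_ids), len(asv_ids)
    sample_host = meta["tissue"].map(TISSUE_TO_HOST).to_numpy()
    sample_season = meta["month"].map(SEASON_MAP).to_numpy()

    base = np.zeros(n_taxa)
    weights = np.zeros((n_real, n_taxa))
    for t, (asv_id, role, _) in enumerate(asv_rows):
        if role == "core":
            base[t] = 10.0 ** rng.normal(2.0, 0.3)       # a few percent each
            weights[:, t] = base[t]
        elif role.startswith("host:"):
            host = role.split(":", 1)[1]
            base[t] = 10.0 ** rng.normal(1.5, 0.3)
            on_host = sample_host == host
            occur = rng.random(n_real) < 0.9
            weights[:, t] = np.where(on_host & occur, base[t], 0.0)
        elif role.startswith("season:"):
            season = role.split(":", 1)[1]
            base[t] = 10.0 ** rng.normal(1.2, 0.3)
            in_season = sample_season == season
            # off-season the taxon is only sporadically detectable
            occur = in_season | (rng.random(n_real)
                                 < config.seasonal_offseason_occurrence)
            fold = np.where(in_season, config.seasonal_fold, 1.0)
            weights[:, t] = np.where(occur, base[t] * fold, 0.0)
        elif role == "background":
            base[t] = 10.0 ** rng.normal(0.8, 0.5)
            occur = rng.random(n_real) < config.background_occurrence
            weights[:, t] = np.where(occur, base[t], 0.0)
        elif role == "organellar":
            base[t] = 10.0 ** rng.normal(1.5, 0.3)
            weights[:, t] = base[t]
        elif role == "contaminant":
            pass  # handled below
    # replicate-level biological noise on nonzero weights
    noise = np.exp(rng.normal(0.0, config.replicate_noise_sd, weights.shape))
    weights *= noise
    if config.dropout > 0:
        keep = rng.random(weights.shape) >= config.dropout
        weights *= keep

    # contaminants: sparse, low relative abundance in real samples
    contam_idx = [asv_ids.index(a) for a in contaminant_asvs]
    row_tot = weights.sum(axis=1)
    for t in contam_idx:
        carriers = rng.choice(n_real, size=min(config.contaminant_freq, n_real),
                              replace=False)
        for s in carriers:
            # weight chosen so the taxon sits near the target relative abundance
            weights[s, t] = row_tot[s] * config.contaminant_relab \
                * np.exp(rng.normal(0.0, 0.3))

    relab_real = weights / weights.sum(axis=1, keepdims=True)

    # control composition: contaminants dominate, plus a trace of background
    ctrl_weights = np.zeros((config.n_controls, n_taxa))
    for s in range(config.n_controls):
        for t in contam_idx:
            ctrl_weights[s, t] = 10.0 ** rng.normal(2.0, 0.3)
        bg_idx = np.flatnonzero(roles.to_numpy() == "background")
        picks = rng.choice(bg_idx, size=min(5, len(bg_idx)), replace=False)
        ctrl_weights[s, picks] = 10.0 ** rng.normal(0.0, 0.3, len(picks))
    relab_ctrl = ctrl_weights / ctrl_weights.sum(axis=1, keepdims=True)

    true_relab = pd.DataFrame(
        np.vstack([relab_real, relab_ctrl]),
        index=pd.Index(real_ids + control_ids, name="sample_id"),
        columns=asv_ids,
    )

    # --- true loads and retained-taxon absolute abundances ------------------
    loads = 10.0 ** rng.normal(config.load_log10_mean, config.load_log10_sd, n_real)
    loads = np.clip(loads, *config.load_clamp)
    true_loads = pd.Series(loads, index=real_ids, name="N")

    retained = [a for a in asv_ids
                if roles[a] not in ("organellar",) and roles[a] != "contaminant"]
    ret_idx = [asv_ids.index(a) for a in retained]
    ret_w = weights[:, ret_idx]
    ret_rel = ret_w / ret_w.sum(axis=1, keepdims=True)
    true_absolute = pd.DataFrame(ret_rel * loads[:, None],
                                 index=pd.Index(real_ids, name="sample_id"),
                                 columns=retained)

    return SyntheticTruth(
        config=config,
        seed=seed,
        metadata=metadata,
        taxonomy=taxonomy,
        roles=roles,
        true_loads=true_loads,
        true_relab=true_relab,
        true_absolute=true_absolute,
        core_genera=core_genera,
        host_specific=host_specific,
        seasonal=seasonal,
        contaminant_asvs=contaminant_asvs,
    )


def simulate_reads(truth: SyntheticTruth, depth: int | None = None,
                   seed: int = 0) -> AsvTable:
    """Multinomial read sampling from each sample's true composition."""
    depth = depth if depth is not None else truth.config.depth
    if depth <= 0:
        raise ValueError("sequencing depth must be positive")
    rng = np.random.default_rng(seed)
    probs = truth.true_relab.to_numpy(float)
    counts = np.vstack([rng.multinomial(depth, p) for p in probs])
    return AsvTable(pd.DataFrame(counts, index=truth.true_relab.index.copy(),
                                 columns=list(truth.true_relab.columns)))


def simulate_qpcr(truth: SyntheticTruth, cv: float | None = None,
                  seed: int = 0) -> pd.DataFrame:
    """qPCR table (copies in reaction + extract concentration) with noise.

    The measured load is the true load times a log-normal factor with
    log-scale sd ``cv``; the emitted copies-in-reaction ``n`` is
    back-computed through the surface-density formula (using the undiluted
    path for extracts below the normalisation target) so downstream
    quantification reconstructs the measured load exactly.
    """
    cv = cv if cv is not None else truth.config.qpcr_cv
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    meta = truth.metadata.table
    rows = []
    for sample_id in truth.real_ids:
        n_true = float(truth.true_loads.loc[sample_id])
        measured = n_true * np.exp(rng.normal(0.0, cv))
        C = float(meta.loc[sample_id, "dna_conc"])
        c_eff = C if C < DEFAULT_C_IN else DEFAULT_C_IN
        n_rxn = measured * c_eff * DEFAULT_V_IN * DEFAULT_SURFACE / (C * DEFAULT_V)
        rows.append({"sample_id": sample_id, "copies_in_reaction": n_rxn, "C": C})
    return pd.DataFrame(rows)


def simulate_env(truth: SyntheticTruth, seed: int = 0) -> pd.DataFrame:
    """Month x environmental-variable table with seasonal structure.

    Variables follow an annual sinusoid (peaking in late summer for
    temperature-like variables) plus noise; a few pairs are generated
    collinear so the pruning step has something to remove.
    """
    from epiquant.io_model import ALL_MONTHS, ENV_VARIABLES

    rng = np.random.default_rng(seed)
    months = list(truth.config.months)
    phase = np.array([ALL_MONTHS.index(m) for m in months]) / 12.0 * 2 * np.pi
    seasonal = np.sin(phase - 2 * np.pi * 8 / 12)  # peak around August
    data = {}
    for i, var in enumerate(ENV_VARIABLES):
        amp = rng.uniform(0.5, 2.0)
        base = rng.uniform(1.0, 20.0)
        data[var] = base + amp * seasonal * (1 if i % 3 else -1) \
            + rng.normal(0, 0.2, len(months))
    env = pd.DataFrame(data, index=pd.Index(months, name="month"))
    # plant collinear pairs: pH tracks T, SiOH4 tracks NO3
    env["pH"] = 8.1 - 0.02 * env["T"] + rng.normal(0, 0.001, len(months))
    env["SiOH4"] = 1.5 * env["NO3"] + rng.normal(0, 0.01, len(months))
    return env


def estimate_fold_change(
    matrix: pd.DataFrame,
    metadata: SampleMetadata,
    taxon: str,
    season_a: str,
    season_b: str,
) -> float:
    """Mean abundance of ``taxon`` in season_a over mean in season_b."""
    meta = metadata.table
    ids_a = [s for s in matrix.index if meta.loc[s, "season"] == season_a]
    ids_b = [s for s in matrix.index if meta.loc[s, "season"] == season_b]
    if not ids_a or not ids_b:
        raise ValueError("both seasons need at least one sample")
    num = float(matrix.loc[ids_a, taxon].mean())
    den = float(matrix.loc[ids_b, taxon].mean())
    if den == 0:
        raise ZeroDivisionError(f"taxon {taxon!r} absent in season {season_b!r}")
    return num / den


def evaluate_recovery(
    truth: SyntheticTruth,
    *,
    core_set: Sequence[str],
    flagged_contaminants: Sequence[str],
    intersections: "Mapping[frozenset[str], int] | None" = None,
    genus_membership: Mapping[str, frozenset[str]] | None = None,
    absolute_genus: pd.DataFrame | None = None,
    relative_genus: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Score pipeline outputs against the planted truth.

    Reports core-detection precision/recall, contaminant precision/recall,
    the fraction of host-specific genera landing in their host's exclusive
    upset cell (``genus_membership`` maps genus -> detected host set), and
    per-seasonal-genus fold-change errors of the quantitative estimate
    versus the relative-abundance-only estimate when the genus-level
    matrices are supplied.
    """
    rows = []
    planted_core = set(truth.core_genera)
    found_core = set(core_set)
    tp = len(planted_core & found_core)
    precision = tp / len(found_core) if found_core else 0.0
    recall = tp / len(planted_core) if planted_core else 1.0
    rows.append({"metric": "core_precision", "value": precision})
    rows.append({"metric": "core_recall", "value": recall})

    planted_cont = set(truth.contaminant_asvs)
    found_cont = set(flagged_contaminants)
    tp_c = len(planted_cont & found_cont)
    rows.append({"metric": "contaminant_precision",
                 "value": tp_c / len(found_cont) if found_cont else 0.0})
    rows.append({"metric": "contaminant_recall",
                 "value": tp_c / len(planted_cont) if planted_cont else 1.0})

    if genus_membership is not None:
        hits = sum(
            1
            for genus, host in truth.host_specific.items()
            if genus_membership.get(genus) == frozenset({host})
        )
        rows.append({"metric": "host_specific_exclusive_fraction",
                     "value": hits / len(truth.host_specific)})

    if absolute_genus is not None and relative_genus is not None:
        reference = "winter"
        for genus, (season, fold) in truth.seasonal.items():
            if season == reference or genus not in absolute_genus.columns:
                continue
            est_q = estimate_fold_change(absolute_genus, truth.metadata, genus,
                                         season, reference)
            est_r = estimate_fold_change(relative_genus, truth.metadata, genus,
                                         season, reference)
            true_fold = estimate_fold_change(
                truth.true_absolute.T.groupby(
                    truth.taxonomy.lineages.loc[truth.true_absolute.columns, "genus"]
                    .to_numpy()
                ).sum().T,
                truth.metadata, genus, season, reference,
            )
            rows.append({"metric": f"fold_error_quantitative:{genus}",
                         "value": abs(np.log(est_q / true_fold))})
            rows.append({"metric": f"fold_error_relative:{genus}",
                         "value": abs(np.log(est_r / true_fold))})
    return pd.DataFrame(rows)


def make_constant_taxon_truth(
    fold: float = 5.0,
    focal_abundance: float = 2e5,
    base_load: float = 2e6,
    n_background: int = 30,
    seed: int = 0,
) -> SyntheticTruth:
    """A confound fixture demonstrating the compositional artifact.

    One focal taxon keeps a constant absolute abundance while the total
    load rises ``fold``-fold from winter to summer (background taxa carry
    the extra mass).  A quantitative pipeline should estimate the focal
    taxon's summer/winter fold change near 1; a relative-abundance-only
    estimate lands near 1/fold.
    """
    config = SyntheticConfig(n_core=0, n_host_specific_per_host=0, n_seasonal=0,
                             n_background=n_background, n_organellar=0,
                             n_contaminants=0, n_controls=1)
    rng = np.random.default_rng(seed)
    design = enumerate_design(config.tissues, config.months, config.replicates,
                              config.deficits)
    real_ids = design["sample_id"].tolist()
    meta = pd.DataFrame(
        {
            "tissue": design["tissue"].to_numpy(),
            "month": design["month"].to_numpy(),
            "replicate": design["replicate"].to_numpy(),
            "dna_conc": 8.0,
            "is_negative_control": False,
        },
        index=pd.Index(real_ids, name="sample_id"),
    )
    metadata = SampleMetadata(meta)
    seasons = meta["month"].map(SEASON_MAP).to_numpy()

    genera = ["ConstFocal"] + [f"Bkg{i + 1:03d}" for i in range(n_background)]
    asv_ids = [f"ASV{i + 1:04d}" for i in range(len(genera))]
    taxonomy = TaxonomyTable(
        pd.DataFrame([_lineage(g) for g in genera],
                     index=pd.Index(asv_ids, name="asv_id"))[list(RANKS)]
    )
    roles = pd.Series(["constant"] + ["background"] * n_background,
                      index=asv_ids, name="role")

    mult = np.where(seasons == "summer", fold, 1.0)
    loads = base_load * mult
    bkg_w = 10.0 ** rng.normal(1.0, 0.4, (len(real_ids), n_background))
    bkg_w *= np.exp(rng.normal(0.0, 0.2, bkg_w.shape))
    bkg_abs = bkg_w / bkg_w.sum(axis=1, keepdims=True) * (loads - focal_abundance)[:, None]
    absolute = np.hstack([np.full((len(real_ids), 1), focal_abundance), bkg_abs])
    relab = absolute / absolute.sum(axis=1, keepdims=True)

    true_relab = pd.DataFrame(relab, index=pd.Index(real_ids, name="sample_id"),
                              columns=asv_ids)
    return SyntheticTruth(
        config=config,
        seed=seed,
        metadata=metadata,
        taxonomy=taxonomy,
        roles=roles,
        true_loads=pd.Series(loads, index=real_ids, name="N"),
        true_relab=true_relab,
        true_absolute=pd.DataFrame(absolute, index=true_relab.index.copy(),
                                   columns=asv_ids),
        core_genera=[],
        host_specific={},
        seasonal={},
        contaminant_asvs=[],
    )


def write_fixture(truth: SyntheticTruth, outdir, reads_seed: int = 0,
                  qpcr_seed: int = 1) -> dict[str, str]:
    """Emit the full file set the pipeline consumes, plus the truth table."""
    from pathlib import Path

    from epiquant import io_model

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reads = simulate_reads(truth, seed=reads_seed)
    qpcr = simulate_qpcr(truth, seed=qpcr_seed)
    env = simulate_env(truth, seed=qpcr_seed + 1)
    paths = {
        "asv_table": outdir / "asv_table.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "metadata": outdir / "metadata.tsv",
        "qpcr": outdir / "qpcr.tsv",
        "env": outdir / "env.tsv",
        "truth": outdir / "truth.tsv",
    }
    io_model.write_asv_table(reads, paths["asv_table"])
    io_model.write_taxonomy(truth.taxonomy, paths["taxonomy"])
    io_model.write_sample_metadata(truth.metadata, paths["metadata"])
    io_model.write_qpcr_table(qpcr, paths["qpcr"])
    io_model.write_env_table(env, paths["env"])
    truth_table = pd.DataFrame({"role": truth.roles})
    truth_table["genus"] = truth.taxonomy.lineages.loc[truth.roles.index, "genus"]
    truth_table.index.name = "asv_id"
    truth_table.to_csv(paths["truth"], sep="\t")
    return {k: str(v) for k, v in paths.items()}
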