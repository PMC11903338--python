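"""End-to-end pipeline: read -> quantify -> filter -> scale -> analyses.

Stages communicate through files so the pipeline composes with external
tools; every run writes a manifest recording stage status, parameters and
SHA-256 hashes of all inputs and outputs, making runs bit-auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from epiquant import community_stats, core_index, io_model, preprocess, qpcr_quant, specificity

logger = logging.getLogger("epiquant")


@dataclasses.dataclass
class PipelineConfig:
    """Paths and parameters of a full run."""

    asv_table: str
    taxonomy: str
    metadata: str
    qpcr: str
    outdir: str
    env: str | None = None

    # qPCR assay constants
    V: float = qpcr_quant.DEFAULT_V
    c: float = qpcr_quant.DEFAULT_C_IN
    v: float = qpcr_quant.DEFAULT_V_IN
    S: float = qpcr_quant.DEFAULT_SURFACE

    # filtering
    organellar_labels: tuple[str, ...] = preprocess.ORGANELLAR_LABELS
    max_freq: int = preprocess.DEFAULT_MAX_FREQ
    max_relab: float = preprocess.DEFAULT_MAX_RELAB

    # core index
    core_threshold: float = core_index.DEFAULT_CORE_THRESHOLD
    detection_threshold: float = core_index.DEFAULT_DETECTION_THRESHOLD

    # permutation statistics
    permutations: int = community_stats.DEFAULT_PERMUTATIONS
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("asv_table", "taxonomy", "metadata", "qpcr"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise FileNotFoundError(f"config input {name!r}: {path} does not exist")
        if self.env is not None and not Path(self.env).exists():
            raise FileNotFoundError(f"config input 'env': {self.env} does not exist")
        for name, lo, hi in (
            ("core_threshold", 0.0, 1.0),
            ("max_relab", 0.0, 1.0),
        ):
            value = getattr(self, name)
            if not (lo < value <= hi):
                raise ValueError(f"config parameter {name}={value} outside ({lo}, {hi}]")
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, config: PipelineConfig) -> None:
        self.stages: list[dict[str, Any]] = []
        self.config = dataclasses.asdict(config)

    def record(self, stage: str, status: str, elapsed: float,
               inputs: dict[str, str], outputs: dict[str, str],
               extra: dict[str, Any] | None = None) -> None:
        entry = {
            "stage": stage,
            "status": status,
            "elapsed_s": round(elapsed, 3),
            "inputs": inputs,
            "outputs": outputs,
        }
        if extra:
            entry["details"] = extra
        self.stages.append(entry)
        logger.info("stage=%s status=%s elapsed=%.2fs outputs=%d",
                    stage, status, elapsed, len(outputs))

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "stages": self.stages}, fh, indent=2,
                      default=str)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages; returns the manifest as a dict.

    Any stage error aborts the run with a :class:`StageError` naming the
    stage; the manifest written so far is preserved in the output
    directory.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config)
    manifest_path = outdir / "manifest.json"

    def stage(name, inputs, fn):
        t0 = time.monotonic()
        try:
            outputs, extra = fn()
        except Exception as exc:  # noqa: BLE001 - stage boundary
            manifest.record(name, "failed", time.monotonic() - t0,
                            {k: _sha256(Path(v)) for k, v in inputs.items()},
                            {}, {"error": str(exc)})
            manifest.write(manifest_path)
            raise StageError(name, exc) from exc
        manifest.record(name, "ok", time.monotonic() - t0,
                        {k: _sha256(Path(v)) for k, v in inputs.items()},
                        {k: _sha256(Path(v)) for k, v in outputs.items()}, extra)
        return outputs

    # --- read --------------------------------------------------------------
    state: dict[str, Any] = {}

    def _read():
        state["table"] = io_model.read_asv_table(config.asv_table)
        state["taxonomy"] = io_model.read_taxonomy(config.taxonomy)
        state["metadata"] = io_model.read_sample_metadata(config.metadata)
        state["qpcr"] = io_model.read_qpcr_table(config.qpcr)
        return {}, {"samples": len(state["table"].sample_ids),
                    "asvs": len(state["table"].asv_ids)}

    stage("read", {"asv_table": config.asv_table, "taxonomy": config.taxonomy,
                   "metadata": config.metadata, "qpcr": config.qpcr}, _read)

    # --- quantify ----------------------------------------------------------
    loads_path = outdir / "loads.tsv"

    def _quantify():
        loads = qpcr_quant.attach_loads(state["metadata"], state["qpcr"],
                                        V=config.V, c=config.c, v=config.v,
                                        S=config.S)
        state["loads"] = loads
        loads.to_csv(loads_path, sep="\t", float_format="%.12g")
        return {"loads": loads_path}, {"flagged": int((loads["flags"] != "").sum())}

    stage("quantify", {"qpcr": config.qpcr}, _quantify)

    # --- filter ------------------------------------------------------------
    filtered_path = outdir / "filtered_counts.tsv"
    contam_path = outdir / "contaminant_report.tsv"
    organellar_path = outdir / "removed_organellar.tsv"

    def _filter():
        table, removed = preprocess.remove_organellar(
            state["table"], state["taxonomy"], config.organellar_labels)
        controls = state["metadata"].control_ids
        report, filtered = preprocess.flag_contaminants(
            table, controls, config.max_freq, config.max_relab)
        state["filtered"] = filtered
        pd.Series(removed, name="asv_id").to_csv(organellar_path, sep="\t",
                                                 index=False)
        header = (f"# contaminant rule: in >=1 control AND frequency <= "
                  f"{config.max_freq} AND max relab <= {config.max_relab}; "
                  f"evaluated after organellar removal\n")
        with open(contam_path, "w") as fh:
            fh.write(header)
            report.table.to_csv(fh, sep="\t", float_format="%.12g")
        io_model.write_asv_table(filtered, filtered_path)
        return (
            {"filtered_counts": filtered_path, "contaminant_report": contam_path,
             "removed_organellar": organellar_path},
            {"organellar_removed": len(removed),
             "contaminants_removed": len(report.flagged)},
        )

    stage("filter", {"asv_table": config.asv_table}, _filter)

    # --- scale -------------------------------------------------------------
    absolute_path = outdir / "absolute_asv.tsv"
    genus_path = outdir / "absolute_genus.tsv"
    excluded_path = outdir / "unassigned_at_genus.tsv"

    def _scale():
        absolute = preprocess.scale_to_absolute(state["filtered"],
                                                state["loads"]["N"])
        pooled, excluded = preprocess.pool_by_rank(absolute, state["taxonomy"],
                                                   "genus")
        state["absolute"] = absolute
        state["absolute_genus"] = pooled
        counts_genus, _ = preprocess.pool_by_rank(state["filtered"].counts,
                                                  state["taxonomy"], "genus")
        state["counts_genus"] = counts_genus
        absolute.values.to_csv(absolute_path, sep="\t", float_format="%.12g")
        pooled.to_csv(genus_path, sep="\t", float_format="%.12g")
        pd.Series(list(excluded.columns), name="asv_id").to_csv(
            excluded_path, sep="\t", index=False)
        return ({"absolute_asv": absolute_path, "absolute_genus": genus_path,
                 "unassigned_at_genus": excluded_path},
                {"genera": pooled.shape[1]})

    stage("scale", {"filtered_counts": filtered_path, "loads": loads_path}, _scale)

    # --- core index --------------------------------------------------------
    core_path = outdir / "core_index.tsv"

    def _core():
        idx = core_index.core_index_table(state["counts_genus"],
                                          state["metadata"],
                                          detection_threshold=config.detection_threshold)
        agg, core = core_index.classify_core(idx, config.core_threshold)
        out = idx.join(agg, rsuffix="_host")
        out.to_csv(core_path, sep="\t", float_format="%.12g")
        state["core"] = core
        return {"core_index": core_path}, {"core_taxa": len(core)}

    stage("core", {"filtered_counts": filtered_path}, _core)

    # --- specificity sets --------------------------------------------------
    upset_genus_path = outdir / "intersections_genus.tsv"
    upset_asv_path = outdir / "intersections_asv.tsv"
    pairs_path = outdir / "shared_pairs.tsv"
    groupcmp_path = outdir / "shared_group_comparison.tsv"

    def _sets():
        ic_genus = specificity.intersection_counts(state["counts_genus"],
                                                   state["metadata"])
        ic_asv = specificity.intersection_counts(state["filtered"].counts,
                                                 state["metadata"])
        ic_genus.to_frame().to_csv(upset_genus_path, sep="\t", index=False)
        ic_asv.to_frame().to_csv(upset_asv_path, sep="\t", index=False)
        pairs = specificity.pairwise_shared(state["filtered"].counts,
                                            state["metadata"])
        pairs.to_csv(pairs_path, sep="\t", index=False)
        cmp_res = specificity.group_comparison(pairs)
        out = cmp_res.pairwise.copy()
        out.insert(0, "omnibus_p", cmp_res.p_value)
        out.insert(0, "omnibus_statistic", cmp_res.statistic)
        out.to_csv(groupcmp_path, sep="\t", index=False, float_format="%.12g")
        return ({"intersections_genus": upset_genus_path,
                 "intersections_asv": upset_asv_path,
                 "shared_pairs": pairs_path,
                 "shared_group_comparison": groupcmp_path},
                {"genus_sets_total": ic_genus.total_detected,
                 "asv_sets_total": ic_asv.total_detected})

    stage("sets", {"filtered_counts": filtered_path}, _sets)

    # --- community statistics ----------------------------------------------
    dist_path = outdir / "bray_curtis.tsv"
    permanova_path = outdir / "permanova.tsv"
    dispersion_path = outdir / "dispersion.tsv"
    richness_path = outdir / "richness.tsv"
    log_load_path = outdir / "log10_loads.tsv"

    def _stats():
        dm = community_stats.bray_curtis(state["absolute"])
        dm.to_data_frame().to_csv(dist_path, sep="\t", float_format="%.12g")
        meta = state["metadata"].table
        rows, disp_rows = [], []
        for factor in ("tissue", "season"):
            groups = meta.loc[list(dm.ids), factor]
            res = community_stats.permanova(dm, groups,
                                            n_perm=config.permutations,
                                            seed=config.seed)
            rows.append({"factor": factor, "scope": "omnibus", "statistic":
                         res.statistic, "p": res.p_value, "r2": res.r_squared,
                         "df_between": res.df_between, "df_within": res.df_within})
            pw = community_stats.pairwise_permanova(dm, groups,
                                                    n_perm=config.permutations,
                                                    seed=config.seed)
            for _, r in pw.iterrows():
                rows.append({"factor": factor,
                             "scope": f"{r['group_a']}|{r['group_b']}",
                             "statistic": r["statistic"], "p": r["p"],
                             "p_adjusted": r["p_adjusted"]})
            disp = community_stats.dispersion(dm, groups,
                                              n_perm=config.permutations,
                                              seed=config.seed)
            for grp, mean in disp.group_means.items():
                disp_rows.append({"factor": factor, "group": grp,
                                  "mean_dispersion": mean,
                                  "statistic": disp.statistic, "p": disp.p_value})
        pd.DataFrame(rows).to_csv(permanova_path, sep="\t", index=False,
                                  float_format="%.12g")
        pd.DataFrame(disp_rows).to_csv(dispersion_path, sep="\t", index=False,
                                       float_format="%.12g")
        rich = community_stats.observed_richness(
            state["filtered"].counts, groupby=meta["tissue"])
        rich.to_csv(richness_path, sep="\t")
        import numpy as np

        log_loads = np.log10(state["loads"]["N"]).rename("log10_N")
        log_loads.to_csv(log_load_path, sep="\t", float_format="%.12g")
        outputs = {"bray_curtis": dist_path, "permanova": permanova_path,
                   "dispersion": dispersion_path, "richness": richness_path,
                   "log10_loads": log_load_path}
        extra = {"permutations": config.permutations, "seed": config.seed}
        if config.env is not None:
            env = io_model.read_env_table(config.env)
            prune = community_stats.env_prune(env)
            env_path = outdir / "env_pruning.tsv"
            with open(env_path, "w") as fh:
                fh.write(f"# retained: {','.join(prune.retained)}\n")
                fh.write(f"# removed: {','.join(prune.removed)}\n")
                prune.report.to_csv(fh, sep="\t", index=False,
                                    float_format="%.12g")
            outputs["env_pruning"] = env_path
            extra["env_removed"] = prune.removed
        return outputs, extra

    stage("stats", {"absolute_asv": absolute_path}, _stats)

    manifest.write(manifest_path)
    return {"config": manifest.config, "stages": manifest.stages,
            "manifest_path": str(manifest_path), "core": state["core"]}
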