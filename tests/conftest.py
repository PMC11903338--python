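import numpy as np
import pandas as pd
import pytest

from epiquant import core_index, preprocess, qpcr_quant
from epiquant import synthetic_data as sd
from epiquant.io_model import SampleMetadata


def make_metadata(rows: dict) -> SampleMetadata:
    """Tiny metadata builder: rows maps sample_id -> (tissue, month, replicate)."""
    df = pd.DataFrame(
        [
            {"tissue": t, "month": m, "replicate": r, "dna_conc": 5.0,
             "is_negative_control": False}
            for (t, m, r) in rows.values()
        ],
        index=pd.Index(list(rows), name="sample_id"),
    )
    return SampleMetadata(df)


@pytest.fixture(scope="session")
def default_truth() -> sd.SyntheticTruth:
    return sd.generate_truth(seed=11)


@pytest.fixture(scope="session")
def default_reads(default_truth):
    return sd.simulate_reads(default_truth, seed=12)


@pytest.fixture(scope="session")
def default_qpcr(default_truth):
    return sd.simulate_qpcr(default_truth, seed=13)


@pytest.fixture(scope="session")
def default_pipeline(default_truth, default_reads, default_qpcr) -> dict:
    """Products of the standard analysis chain on the default fixture."""
    truth = default_truth
    loads = qpcr_quant.attach_loads(truth.metadata, default_qpcr)
    table, organellar = preprocess.remove_organellar(default_reads, truth.taxonomy)
    report, filtered = preprocess.flag_contaminants(
        table, truth.metadata.control_ids)
    absolute = preprocess.scale_to_absolute(filtered, loads["N"])
    genus_abs, _ = preprocess.pool_by_rank(absolute, truth.taxonomy, "genus")
    genus_counts, _ = preprocess.pool_by_rank(filtered.counts, truth.taxonomy,
                                              "genus")
    index = core_index.core_index_table(genus_counts, truth.metadata)
    agg, core = core_index.classify_core(index)
    rel_genus = genus_counts.div(genus_counts.sum(axis=1), axis=0)
    return {
        "loads": loads,
        "organellar": organellar,
        "report": report,
        "filtered": filtered,
        "absolute": absolute,
        "genus_abs": genus_abs,
        "genus_counts": genus_counts,
        "rel_genus": rel_genus,
        "index": index,
        "agg": agg,
        "core": core,
    }
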