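import pytest

from isoprobe.cluster_builder import GeneModel, build_clusters
from isoprobe.probe_mapping import build_match_index, classify_probes, map_probes
from isoprobe.synthetic_fixtures import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """One synthetic study at default conditions, shared across tests."""
    config = SimulationConfig(seed=42)
    transcripts, probes, truth, matrix = simulate_study(config)
    return config, transcripts, probes, truth, matrix


@pytest.fixture(scope="session")
def mapped_study(default_study):
    """The default study taken through mapping, classification, clustering."""
    config, transcripts, probes, truth, matrix = default_study
    index = build_match_index(transcripts)
    hits = map_probes(probes, index)
    classes = classify_probes(probes, hits)
    model = GeneModel.from_transcripts(transcripts)
    clusters = build_clusters(classes, hits, model)
    return {
        "config": config,
        "transcripts": transcripts,
        "probes": probes,
        "truth": truth,
        "matrix": matrix,
        "index": index,
        "hits": hits,
        "classes": classes,
        "model": model,
        "clusters": clusters,
    }
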