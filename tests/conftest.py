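import pandas as pd
import pytest

from hgtscan import (
    PipelineConfig, TaxonomyDB, WorldConfig, generate_world, run_pipeline,
)


def _toy_lineages():
    """Hand-built taxonomy: a fungal recipient with a congeneric cousin,
    other fungi, bacteria of two phyla, an archaeon and a virus."""
    rows = {
        "Amanita_recipiens": ("Eukaryota", "Basidiomycota", "Agaricomycetes",
                              "Agaricales", "Amanitaceae", "Amanita"),
        "Amanita_cousina": ("Eukaryota", "Basidiomycota", "Agaricomycetes",
                            "Agaricales", "Amanitaceae", "Amanita"),
        "Fusarium_aliud": ("Eukaryota", "Ascomycota", "Sordariomycetes",
                           "Hypocreales", "Nectriaceae", "Fusarium"),
        "Coprinus_alter": ("Eukaryota", "Basidiomycota", "Agaricomycetes",
                           "Agaricales", "Psathyrellaceae", "Coprinus"),
        "Escherichia_coli": ("Bacteria", "Proteobacteria",
                             "Gammaproteobacteria", "Enterobacterales",
                             "Enterobacteriaceae", "Escherichia"),
        "Pseudomonas_putida": ("Bacteria", "Proteobacteria",
                               "Gammaproteobacteria", "Pseudomonadales",
                               "Pseudomonadaceae", "Pseudomonas"),
        "Streptomyces_grisea": ("Bacteria", "Actinobacteria",
                                "Actinomycetia", "Streptomycetales",
                                "Streptomycetaceae", "Streptomyces"),
        "Halobacterium_salinarum": ("Archaea", "Euryarchaeota", "Halobacteria",
                                    "Halobacteriales", "Halobacteriaceae",
                                    "Halobacterium"),
        "Phikmvvirus_alpha": ("Viruses", "Uroviricota", "Caudoviricetes",
                              "Caudovirales", "Autographiviridae",
                              "Phikmvvirus"),
    }
    return {sp: (*lin, sp) for sp, lin in rows.items()}


@pytest.fixture(scope="session")
def toy_taxonomy() -> TaxonomyDB:
    return TaxonomyDB(lineages=_toy_lineages())


@pytest.fixture(scope="session")
def small_world(tmp_path_factory):
    """A compact world with sequence content for genome_00 (intron origin
    search) shared across module tests."""
    root = tmp_path_factory.mktemp("small_world")
    cfg = WorldConfig(seed=42, n_genomes=6, genes_per_genome=250,
                      sequence_genomes=("genome_00",))
    truth = generate_world(cfg, root)
    return {"cfg": cfg, "truth": truth, "path": root}


@pytest.fixture(scope="session")
def small_world_run(small_world):
    report, artifacts = run_pipeline(
        small_world["path"], PipelineConfig(n_perm=199, seed=1))
    return {"report": report, "artifacts": artifacts, **small_world}


@pytest.fixture(scope="session")
def default_world(tmp_path_factory):
    """The default study conditions: ~50 genomes x 2000 genes, ~2% planted
    transfers.  Session-scoped because generation takes ~1 min."""
    root = tmp_path_factory.mktemp("default_world")
    cfg = WorldConfig(seed=20240901)
    truth = generate_world(cfg, root)
    return {"cfg": cfg, "truth": truth, "path": root}


@pytest.fixture(scope="session")
def default_world_run(default_world):
    report, artifacts = run_pipeline(
        default_world["path"],
        PipelineConfig(n_perm=199, seed=1, run_traits=True))
    return {"report": report, "artifacts": artifacts, **default_world}
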