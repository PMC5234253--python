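import pytest
from hypothesis import settings

settings.register_profile("ci", max_examples=50, derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run under the reference study conditions
    (12 leaves, 6 post-WGD, 30 background families, retention 0.9, seed 1).

    Session-scoped: the end-to-end and determinism checks share it.
    """
    from ohnotrace.pipeline import default_simulated_config, run

    outdir = tmp_path_factory.mktemp("default_run")
    summary = run(default_simulated_config(outdir, seed=1))
    return summary, outdir


@pytest.fixture()
def tiny_db():
    """Two hand-built genomes (one pre-, one post-WGD) with known layout."""
    from ohnotrace.genome_db import GenomeDB, GenomeRecord, OrfRecord

    def orf(code, strain, local, scaf, ordinal, seq, strand="+"):
        return OrfRecord(
            f"{code}_{strain}_g{local}", code, strain, scaf, ordinal, strand, seq
        )

    pre = GenomeRecord(
        "prea", 1, "pre",
        [orf("prea", 1, i, "s1", i, seq) for i, seq in enumerate(["MKVLA", "MACDE", "MWWWC", "MKKKK"])],
    )
    post = GenomeRecord(
        "posa", 1, "post",
        [orf("posa", 1, 0, "s1", 0, "MKVLA"), orf("posa", 1, 1, "s1", 1, "MACDE"),
         orf("posa", 1, 2, "s2", 0, "MWWWC")],
    )
    return GenomeDB([pre, post])
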