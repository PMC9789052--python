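import numpy as np
import pytest

from ntescan import extension as E
from ntescan import ribo as R
from ntescan.pipeline import simulate_inputs
from ntescan.simulate import SimConfig, demo_config, gen_ribo_profiles, gen_transcriptome
from ntescan.transcript_io import attach_exons, parse_transcript_fasta


@pytest.fixture(scope="session")
def demo_bundle(tmp_path_factory):
    """The seed-7 demonstration input bundle on disk."""
    d = tmp_path_factory.mktemp("demo")
    paths = simulate_inputs(demo_config(), d)
    return d, paths


@pytest.fixture(scope="session")
def demo_records(demo_bundle):
    _, paths = demo_bundle
    records, _ = parse_transcript_fasta(paths["fasta"])
    return attach_exons(records, paths["gtf"])


@pytest.fixture(scope="session")
def detection_cohort():
    """In-memory cohort at the planted-signal defaults: 50 true extensions
    among 450 decoys, depth 10 reads/codon, frame-0 bias 0.8, step 5."""
    cfg = SimConfig(seed=11, n_genes=500, fraction_true_nte=0.1)
    records, truth = gen_transcriptome(cfg)
    raw = gen_ribo_profiles(records, truth, cfg)
    profiles = {t: R.RiboProfile(t, v["elong"], v["init"]) for t, v in raw.items()}
    rec_by = {r.transcript_id: r for r in records}
    exts, cands, cds = {}, {}, {}
    for r in records:
        ext, _ = E.extract_theoretical_extension(r)
        if ext is None or ext.length_codons < 20:
            continue
        exts[r.transcript_id] = ext
        cands[r.transcript_id] = E.enumerate_candidate_starts(E.clip_window(ext, r))
        cds[r.transcript_id] = r.cds_start
    for t, p in profiles.items():
        p.length = len(rec_by[t].sequence)
    return dict(cfg=cfg, records=records, truth=truth, profiles=profiles,
                extensions=exts, candidates=cands, cds_starts=cds)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
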