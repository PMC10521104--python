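"""Shared fixtures: synthetic corpora and one full pipeline run per session.

The end-to-end fixtures are session-scoped because conformer generation and
overlay optimization dominate runtime; every test reads from the same run.
"""
from __future__ import annotations

import json
from pathlib import Path

import pytest

from ligscreen.pipeline import PipelineConfig, run_pipeline
from ligscreen.shape import ConformerPolicy
from ligscreen.states import oxindole_state_space
from ligscreen.synthetic import SyntheticConfig, generate_corpora

#: validation-scale conformer ensembles (small on purpose; the policy object
#: itself defaults to full screening scale)
DESK_POLICY = dict(n_query_default=2, n_ref_chembl=2, n_ref_drugbank=2,
                   n_query_vs_pdb=2)


@pytest.fixture(scope="session")
def oxindole_space():
    return oxindole_state_space()


@pytest.fixture(scope="session")
def synth_dir(tmp_path_factory, oxindole_space) -> Path:
    """Default-configuration synthetic corpora + manifest (fixed seed)."""
    outdir = tmp_path_factory.mktemp("synth")
    config = SyntheticConfig()
    generate_corpora(config, oxindole_space, outdir)
    return outdir


@pytest.fixture(scope="session")
def manifest(synth_dir) -> dict:
    return json.loads((synth_dir / "manifest.json").read_text())


def _pipeline_config(synth_dir: Path) -> PipelineConfig:
    return PipelineConfig(
        drugbank_path=str(synth_dir / "drugbank.csv"),
        pdb_path=str(synth_dir / "pdb.sdf"),
        chembl_path=str(synth_dir / "chembl.csv"),
        seed=SyntheticConfig().seed,
        conformers=ConformerPolicy(**DESK_POLICY),
    )


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory, synth_dir):
    """One full pipeline run over the synthetic corpora."""
    outdir = tmp_path_factory.mktemp("run_a")
    return run_pipeline(_pipeline_config(synth_dir), outdir)


@pytest.fixture(scope="session")
def pipeline_rerun(tmp_path_factory, synth_dir):
    """A second, independent run with identical config + seed."""
    outdir = tmp_path_factory.mktemp("run_b")
    return run_pipeline(_pipeline_config(synth_dir), outdir)
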