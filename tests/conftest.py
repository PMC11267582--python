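from __future__ import annotations

import pandas as pd
import pytest

from pvsignal import GeneratorConfig, generate_dataset, load_case_set
from pvsignal.ingest import CaseReport, DrugEntry


def make_case(
    primaryid: int,
    reactions: list[str],
    caseid: int | None = None,
    sex: str = "unknown",
    drug: str = "TILDRAKIZUMAB",
    role: str = "PS",
    therapy_start: str = "",
    event_dt: str = "",
    **kwargs,
) -> CaseReport:
    """Minimal hand-built report for unit fixtures."""
    return CaseReport(
        primaryid=primaryid,
        caseid=caseid if caseid is not None else primaryid,
        fda_dt="20230101",
        event_dt=event_dt,
        sex=sex,
        drugs=[DrugEntry(name=drug, role=role, therapy_start=therapy_start)],
        reactions=list(reactions),
        **kwargs,
    )


@pytest.fixture(scope="session")
def shared_config() -> GeneratorConfig:
    return GeneratorConfig(n_reports=8000, seed=11, target_prob=0.05)


@pytest.fixture(scope="session")
def shared_fileset(shared_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("synth_shared")
    return generate_dataset(shared_config, out)


@pytest.fixture(scope="session")
def shared_ledger_cases(shared_fileset) -> pd.DataFrame:
    return shared_fileset.load_ledger_cases()


@pytest.fixture(scope="session")
def shared_ledger_pts(shared_fileset) -> pd.DataFrame:
    return shared_fileset.load_ledger_pts()


@pytest.fixture(scope="session")
def shared_clean(shared_fileset):
    """(target, background, cleaning_report) for the shared synthetic set."""
    return load_case_set(shared_fileset.out_dir)
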