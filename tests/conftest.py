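"""Shared fixtures: small hand-built frames and seeded synthetic registries."""

import io

import pandas as pd
import pytest
from hypothesis import settings

import laolink as ll

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_frame(rows):
    """Build a raw registry frame from dicts (record_id auto-filled)."""
    base = {c: None for c in ll.records.RAW_COLUMNS}
    data = []
    for i, row in enumerate(rows):
        rec = dict(base)
        rec["record_id"] = f"r{i:03d}"
        rec.update(row)
        data.append(rec)
    return pd.DataFrame(data, columns=ll.records.RAW_COLUMNS)


def roundtrip_read(df):
    """Push a frame through the CSV reader so dtypes match file input."""
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    buf.seek(0)
    return ll.read_records(buf)


def normalized(df):
    return ll.LaoNameNormalizer().fit_transform(roundtrip_read(df))


@pytest.fixture(scope="session")
def small_registry():
    """n=2000 synthetic registry with truth, normalized."""
    cfg = ll.GeneratorConfig(n_records=2000)
    df, truth = ll.generate_registry(cfg, seed=7)
    return normalized(df), truth


@pytest.fixture(scope="session")
def paper_scale_registry():
    """Full-size (n=20433) synthetic registry at default study conditions."""
    df, truth = ll.generate_registry(ll.GeneratorConfig(), seed=11)
    return normalized(df), truth


@pytest.fixture(scope="session")
def paper_scale_results(paper_scale_registry):
    """Fitted deterministic / probabilistic / hybrid matchers at full size."""
    norm, truth = paper_scale_registry
    det = ll.DeterministicMatcher().fit(norm)
    prob = ll.FellegiSunterMatcher().fit(norm)
    hyb = ll.HybridMatcher().fit(norm)
    return {"norm": norm, "truth": truth, "det": det, "prob": prob, "hyb": hyb}
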