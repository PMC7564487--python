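import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from thyrofish.core import AcghProfile, build_probe_set
from thyrofish.genome import load_default_genome

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def genome():
    return load_default_genome()


@pytest.fixture()
def toy_cytoband(tmp_path):
    """Two adjacent p bands on chr1."""
    path = tmp_path / "cyto.tsv"
    path.write_text(
        "chr1\t0\t50\tp36.33\tgneg\n"
        "chr1\t50\t100\tp36.32\tgneg\n"
    )
    return path


def make_probes(n_per_chrom=50, chroms=("1", "2"), spacing=100, gc=None):
    ids, cs, starts, ends, gcs = [], [], [], [], []
    for c in chroms:
        for i in range(n_per_chrom):
            ids.append(f"p{c}_{i}")
            cs.append(c)
            starts.append(i * spacing)
            ends.append(i * spacing + 60)
            gcs.append(0.5 if gc is None else gc[len(gcs)])
    return build_probe_set(ids, cs, starts, ends, gcs)


@pytest.fixture()
def flat_probes():
    return make_probes()


def profile_from(values, sample_id="S1", **kw):
    return AcghProfile(sample_id=sample_id, values=np.asarray(values, float), **kw)
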