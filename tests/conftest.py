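import numpy as np
import pytest

import nirseed as ns


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def _tiny_metadata(n_bags, scans_per_bag=2):
    cultivars = ["Alto", "Bronsyn", "Maxsyn", "Trojan"]
    meta = []
    for b in range(n_bags):
        cultivar = cultivars[b % 4]
        strain = "WE" if b % 3 == 0 else "AR1"
        status = "E-" if strain == "WE" else "E+"
        for k in range(1, scans_per_bag + 1):
            meta.append(ns.ScanMetadata(
                bag_id=f"b{b}", cultivar=cultivar, endophyte_strain=strain,
                endophyte_status=status, scan_index=k))
    return meta


@pytest.fixture()
def small_set(rng):
    """12 scans (6 bags x 2) on a short 10-point grid."""
    grid = ns.build_grid(100, 28, 8)
    meta = _tiny_metadata(6, scans_per_bag=2)
    X = rng.normal(0.5, 0.1, size=(len(meta), grid.n_points))
    return ns.SpectraSet(grid=grid, absorbance=X, metadata=meta)


@pytest.fixture(scope="session")
def benchmark():
    """The canonical 100-bag benchmark, generated once per session."""
    spectra, truth, bounds = ns.benchmark_suite(seed=1)
    return spectra, truth, bounds


@pytest.fixture(scope="session")
def combined_result(benchmark):
    """Trained combined cultivar+endophyte model on the benchmark."""
    from nirseed import workflow as wf

    spectra, _, _ = benchmark
    return wf.train_combined(spectra)
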