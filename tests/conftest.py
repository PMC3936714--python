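import numpy as np
import pytest

import oriscope as o
from oriscope.genome_io import GenomeAssembly, Replicon


@pytest.fixture(scope="session")
def oric1_build():
    return o.build_from_config("hhis_oriC1_mimic")


@pytest.fixture(scope="session")
def oric2_build():
    return o.build_from_config("hhis_oriC2_mimic")


@pytest.fixture(scope="session")
def hla_build():
    return o.build_from_config("hla_oriC2_mimic")


class TwoOriginSetup:
    """A 120-kb circular replicon with two antipodally opposed origins and a
    2 probes/kb array; the geometry used throughout the MFA tests."""

    L = 120_000
    tau = 120.0
    o1 = 20_000
    o2 = 80_000

    def __init__(self):
        self.assembly = GenomeAssembly(
            (Replicon("chr_mimic", "ACGT" * (self.L // 4)),)
        )
        self.design = o.design_probes(self.assembly, min_density=2.0, seed=3)
        self.positions = self.design.positions("chr_mimic")
        self.d_ter = 30_000.0  # farthest point from the nearest origin

    def program(self, p1: float, p2: float,
                fork_speed: float = 300.0) -> o.ReplicationProgram:
        return o.ReplicationProgram(
            replicon_id="chr_mimic",
            replicon_length=self.L,
            origins=(
                o.OriginActivity(self.o1, p1),
                o.OriginActivity(self.o2, p2),
            ),
            fork_speed=fork_speed,
            doubling_time=self.tau,
        )

    def spacing(self) -> float:
        return float(np.median(np.diff(self.positions)))

    def nearest_probe(self, position: int) -> int:
        d = np.abs(self.positions - position)
        d = np.minimum(d, self.L - d)
        return int(self.positions[np.argmin(d)])


@pytest.fixture(scope="session")
def two_origin():
    return TwoOriginSetup()


@pytest.fixture(scope="session")
def demo_result(tmp_path_factory):
    from oriscope.cli import DemoConfig, run_demo

    outdir = tmp_path_factory.mktemp("demo")
    ok, report = run_demo(DemoConfig(outdir=outdir, seed=7))
    return ok, report, outdir
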