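import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def demo_case():
    """The offline trypsinogen design demonstration (target, synthetic
    homolog, synthetic model); built once per session."""
    from zymocharge.synthetic_homolog import demo_design_case

    return demo_design_case()


@pytest.fixture(scope="session")
def demo_report(demo_case):
    from zymocharge.design import propose_charge_transfer

    return propose_charge_transfer(
        demo_case.target,
        demo_case.homolog,
        demo_case.structure,
        demo_case.constraints,
        transfer_mode="extended",
    )
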