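import numpy as np
import pytest

from synergyci import ConstantRatioDesign, MedianEffectFit


@pytest.fixture
def curcumin_flavocoxid_design() -> ConstantRatioDesign:
    """Curcumin + flavocoxid constant-ratio design (molar ratio 1:7.3, µM)."""
    return ConstantRatioDesign(
        fit1=MedianEffectFit(dm=14.28, m=1.835),
        fit2=MedianEffectFit(dm=91.2, m=2.005),
        fit12=MedianEffectFit(dm=26.3, m=1.816),
        ratio=(1.0, 7.3),
        agent1="curcumin",
        agent2="flavocoxid",
    )


@pytest.fixture
def curcumin_bcp_design() -> ConstantRatioDesign:
    """Curcumin + β-caryophyllene constant-ratio design (molar ratio 1:3.6, µM)."""
    return ConstantRatioDesign(
        fit1=MedianEffectFit(dm=13.57, m=1.38),
        fit2=MedianEffectFit(dm=48.93, m=0.88),
        fit12=MedianEffectFit(dm=28.28, m=1.73),
        ratio=(1.0, 3.6),
        agent1="curcumin",
        agent2="bcp",
    )


# Published CI tabulations for the two designs (fa -> CI).
CURCUMIN_FLAVOCOXID_CI = {
    0.05: 0.43, 0.10: 0.44, 0.20: 0.45, 0.30: 0.46, 0.40: 0.47, 0.50: 0.47,
    0.60: 0.48, 0.70: 0.49, 0.80: 0.50, 0.90: 0.51, 0.95: 0.52,
}
CURCUMIN_BCP_CI = {
    0.10: 2.1677, 0.20: 1.5360, 0.30: 1.2389, 0.40: 1.0480, 0.50: 0.9053,
    0.60: 0.7876, 0.70: 0.6820, 0.80: 0.5783, 0.90: 0.4609,
}
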