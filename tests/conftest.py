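import numpy as np
import pytest

from abselect.annotation import AnnotatedClone, ScaffoldRef
from abselect.simulate import CampaignConfig, simulate_campaign


@pytest.fixture(scope="session")
def toy_scaffold() -> ScaffoldRef:
    return ScaffoldRef(
        name="IGHV-TOY::IGKV-TOY",
        vl_frameworks=("DIQMTQSPSSLSA", "WYQQKPGKAP", "GVPSRFSGSGSGTD", "FGQGTKVEIK"),
        vh_frameworks=("EVQLVESGGGLVQP", "WVRQAPGKGL", "RFTISRDNSKNTLY", "WGQGTLVTVSS"),
        linker="GGGGSGGGGS",
    )


@pytest.fixture(scope="session")
def toy_scaffold_b() -> ScaffoldRef:
    return ScaffoldRef(
        name="IGHV-ALT::IGLV-ALT",
        vl_frameworks=("QSVLTQPPSVSAA", "WYQQLPGTAP", "GVPDRFSGSKSGTS", "FGGGTKLTVL"),
        vh_frameworks=("QVQLQESGPGLVKP", "WIRQPPGKGL", "RVTISVDTSKNQFS", "WGRGTLVTVSS"),
        linker="GGGGSGGGGS",
    )


TOY_CDRS = {
    "LCDR1": "QSISSY",
    "LCDR2": "AASSLQS",
    "LCDR3": "QQSYSTPLT",
    "HCDR1": "GFTFSSYA",
    "HCDR2": "ISGSGGST",
    "HCDR3": "ARDYWGQGHF",
}


def make_clone(
    scaffold: ScaffoldRef,
    cdrs: dict | None = None,
    clone_id: str = "c1",
    counts: dict | None = None,
    liabilities: int = 0,
    **cdr_overrides,
) -> AnnotatedClone:
    cdrs = dict(cdrs or TOY_CDRS)
    cdrs.update(cdr_overrides)
    vl, vh = scaffold.vl_frameworks, scaffold.vh_frameworks
    frameworks = {
        "LFR1": vl[0], "LFR2": vl[1], "LFR3": vl[2], "LFR4": vl[3],
        "LINKER": scaffold.linker,
        "HFR1": vh[0], "HFR2": vh[1], "HFR3": vh[2], "HFR4": vh[3],
    }
    return AnnotatedClone(
        clone_id=clone_id,
        aa_full=scaffold.assemble(cdrs),
        scaffold=scaffold.name,
        cdrs=cdrs,
        frameworks=frameworks,
        counts=dict(counts or {"10nM": 1}),
        liabilities=liabilities,
    )


@pytest.fixture(scope="session")
def clone_factory():
    return make_clone


@pytest.fixture(scope="session")
def small_campaign():
    """Desk-scale campaign with sequencing errors and known ground truth."""
    cfg = CampaignConfig(seed=11, n_families=8, reads_per_population=1500)
    return simulate_campaign(cfg)


def reverse_translate(aa: str, seed: int = 0) -> str:
    from abselect.simulate import _reverse_translate

    return _reverse_translate(np.random.default_rng(seed), aa)


@pytest.fixture(scope="session")
def rev_translate():
    return reverse_translate
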