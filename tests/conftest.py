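import pytest

from pahrisk import CampaignDesign, PEFTable, WaterSample, generate_campaign


def make_sample(conc=None, nondetect=None, **meta):
    """A water sample with every carcinogen measured (ND unless given)."""
    conc = dict(conc or {})
    nondetect = {a: True for a in ("BaA", "Chy", "BaP", "BbF", "BkF", "DahA", "IcdP")
                 if a not in conc}
    defaults = dict(village_id="V01", group="risk", water_type="SW", season="winter")
    defaults.update(meta)
    return WaterSample(conc=conc, nondetect=nondetect, **defaults)


@pytest.fixture(scope="session")
def pefs():
    return PEFTable()


@pytest.fixture(scope="session")
def small_campaign():
    """A 6-village campaign (fast, censored, fixed seed)."""
    design = CampaignDesign(n_villages_per_group=3, seed=11)
    return generate_campaign(design)
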