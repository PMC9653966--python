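import base64

import numpy as np
import pytest

from leda_ms import SynthConfig, builtin_ratio_table


@pytest.fixture(scope="session")
def fra_table():
    """FRA76/GDE5 characteristic-ratio table (precursor m/z 590)."""
    return builtin_ratio_table("fra76_gde5")


@pytest.fixture(scope="session")
def elf_table():
    """ELF94/ELF96 characteristic-ratio table (precursor m/z 604)."""
    return builtin_ratio_table("elf94_elf96")


@pytest.fixture
def clean_config(elf_table):
    """Noise-free generator at the standard study conditions."""
    return SynthConfig(seed=0, noise_cv=0.0, ratio_table=elf_table)


@pytest.fixture
def noisy_config(elf_table):
    """Default 2% channel-area CV, fixed seed."""
    return SynthConfig(seed=42, noise_cv=0.02, ratio_table=elf_table)


FIVE_LEVELS = [0.90, 0.75, 0.50, 0.25, 0.10]


def _b64(values):
    return base64.b64encode(np.asarray(values, dtype="<f8").tobytes()).decode()


def _mzml_chromatogram(cid, index, precursor, product, cv, times, intensities):
    return f"""<chromatogram id="{cid}" index="{index}" defaultArrayLength="{len(times)}">
<precursor><isolationWindow>
<cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="{precursor}"/>
</isolationWindow><activation>
<cvParam cvRef="MS" accession="MS:1000045" name="collision energy" value="{cv}"/>
</activation></precursor>
<product><isolationWindow>
<cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="{product}"/>
</isolationWindow></product>
<binaryDataArrayList count="2">
<binaryDataArray><cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>
<cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>
<cvParam cvRef="MS" accession="MS:1000595" name="time array" unitName="minute"/>
<binary>{_b64(times)}</binary></binaryDataArray>
<binaryDataArray><cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>
<cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>
<cvParam cvRef="MS" accession="MS:1000515" name="intensity array"/>
<binary>{_b64(intensities)}</binary></binaryDataArray>
</binaryDataArrayList></chromatogram>"""


def write_srm_mzml(path, transitions):
    """Write a minimal synthetic mzML with one SRM chromatogram per entry.

    ``transitions`` is a list of (precursor_mz, product_mz, cv, times,
    intensities) tuples.
    """
    chroms = "\n".join(
        _mzml_chromatogram(
            f"SRM {prec:g}->{prod:g}", i, prec, prod, cv, times, intensities
        )
        for i, (prec, prod, cv, times, intensities) in enumerate(transitions)
    )
    doc = f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0" id="synthetic">
<run id="run1"><chromatogramList count="{len(transitions)}" defaultDataProcessingRef="dp1">
{chroms}
</chromatogramList></run></mzML>"""
    path.write_text(doc)
    return path
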