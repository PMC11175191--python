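"""Shared fixtures: small synthetic datasets and a minimal EDF writer."""

from __future__ import annotations

import struct

import numpy as np
import pytest

from fuzzygcn.data import EpochSet
from fuzzygcn.simulate import make_fixture


@pytest.fixture(scope="session")
def tiny_set() -> EpochSet:
    es, _ = make_fixture("tiny", seed=7)
    return es


@pytest.fixture(scope="session")
def default_set() -> EpochSet:
    es, _ = make_fixture("default", seed=1)
    return es


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def write_minimal_edf(path, data_uv: np.ndarray, channel_names: list[str],
                      fs: float) -> None:
    """Write a single-record EDF file (synthetic test fixture).

    Implements just enough of the European Data Format: the 256-byte main
    header, one 256-byte signal-header block per channel, and a single data
    record of little-endian int16 samples scaled into a +/-200 uV physical
    range. ``data_uv.shape[1] / fs`` must be a whole number of seconds.
    """
    n_ch, n_samp = data_uv.shape
    duration = n_samp / fs
    assert duration == int(duration), "need an integer record duration"
    phys_min, phys_max = -200.0, 200.0
    dig_min, dig_max = -32768, 32767

    def pad(value: str, width: int) -> bytes:
        b = value.encode("ascii")
        assert len(b) <= width
        return b + b" " * (width - len(b))

    header = b"".join([
        pad("0", 8),                     # version
        pad("X X X X", 80),              # patient id
        pad("Startdate 01-JAN-2020 X X X", 80),   # recording id
        pad("01.01.20", 8), pad("00.00.00", 8),   # start date/time
        pad(str(256 * (1 + n_ch)), 8),   # header byte count
        pad("", 44),                     # reserved
        pad("1", 8),                     # number of data records
        pad(str(int(duration)), 8),      # record duration (s)
        pad(str(n_ch), 4),               # number of signals
    ])
    fields = [
        [pad(name, 16) for name in channel_names],
        [pad("AgAgCl electrode", 80)] * n_ch,
        [pad("uV", 8)] * n_ch,
        [pad(str(phys_min), 8)] * n_ch,
        [pad(str(phys_max), 8)] * n_ch,
        [pad(str(dig_min), 8)] * n_ch,
        [pad(str(dig_max), 8)] * n_ch,
        [pad("", 80)] * n_ch,
        [pad(str(n_samp), 8)] * n_ch,
        [pad("", 32)] * n_ch,
    ]
    sig_header = b"".join(b"".join(col) for col in fields)

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(np.round((data_uv - phys_min) * scale + dig_min),
                      dig_min, dig_max).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for ch in range(n_ch):
            fh.write(struct.pack(f"<{n_samp}h", *digital[ch]))
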