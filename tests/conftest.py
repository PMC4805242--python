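"""Shared fixtures: small event matrices and an independent FCS writer."""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pytest

from cytoemd import EventMatrix


def write_fcs(
    path: Path,
    values: np.ndarray,
    channels: list[str],
    datatype: str = "F",
    little_endian: bool = True,
) -> Path:
    """Write a minimal FCS 3.0 list-mode file.

    Deliberately independent of the package reader: the byte layout is
    assembled by hand from the published segment structure so that reading
    it back is a genuine round-trip check.
    """
    values = np.asarray(values)
    n_tot, n_par = values.shape
    if datatype == "F":
        dtype, bits = ("<f4" if little_endian else ">f4"), 32
    elif datatype == "D":
        dtype, bits = ("<f8" if little_endian else ">f8"), 64
    elif datatype == "I":
        dtype, bits = ("<u4" if little_endian else ">u4"), 32
    else:
        raise ValueError(datatype)
    data = values.astype(dtype).tobytes()

    byteord = "1,2,3,4" if little_endian else "4,3,2,1"
    pairs = {
        "$MODE": "L",
        "$DATATYPE": datatype,
        "$BYTEORD": byteord,
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
        "$NEXTDATA": "0",
    }
    for i, name in enumerate(channels, start=1):
        pairs[f"$P{i}N"] = name
        pairs[f"$P{i}B"] = str(bits)
        pairs[f"$P{i}E"] = "0,0"
        pairs[f"$P{i}R"] = "262144"
    delim = "/"
    text = delim + delim.join(f"{k}{delim}{v}" for k, v in pairs.items()) + delim
    text_bytes = text.encode("ascii")

    header_len = 58
    text_start = header_len
    text_end = text_start + len(text_bytes) - 1
    data_start = text_end + 1
    data_end = data_start + len(data) - 1
    header = (
        b"FCS3.0    "
        + f"{text_start:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + f"{data_start:>8d}".encode()
        + f"{data_end:>8d}".encode()
        + f"{0:>8d}".encode()
        + f"{0:>8d}".encode()
    )
    assert len(header) == header_len
    path.write_bytes(header + text_bytes + data)
    return path


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160323)


@pytest.fixture
def small_events() -> EventMatrix:
    values = np.array(
        [
            [0.0, 0.0],
            [0.0, 10.0],
            [0.0, 20.0],
            [0.0, 30.0],
        ]
    )
    return EventMatrix(values, ("CD63", "CD203c"))


@pytest.fixture
def gaussian_events(rng) -> EventMatrix:
    return EventMatrix(rng.normal(0.0, 1.0, size=(2000, 2)), ("CD203c", "CD63"))


def random_signature(
    rng: np.random.Generator,
    n_bins: int,
    n_dims: int,
    denominator: int | None = None,
):
    """Random signature; with ``denominator`` the weights are rationals k/L."""
    from cytoemd import Signature

    centroids = rng.normal(0.0, 2.0, size=(n_bins, n_dims))
    if denominator is None:
        weights = rng.dirichlet(np.ones(n_bins))
    else:
        counts = rng.multinomial(denominator, np.ones(n_bins) / n_bins)
        while (counts == 0).all():  # pragma: no cover - defensive
            counts = rng.multinomial(denominator, np.ones(n_bins) / n_bins)
        keep = counts > 0
        centroids, counts = centroids[keep], counts[keep]
        weights = counts / denominator
    return Signature(centroids, weights)
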