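import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import geowave as gw

settings.register_profile(
    "ci",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def write_minimal_fcs(path, values, names):
    """Write a minimal FCS 3.0 list-mode file (float32, little-endian).

    Test-only synthetic fixture writer; the package itself only reads FCS.
    """
    values = np.asarray(values, dtype="<f4")
    n_tot, n_par = values.shape
    data = values.tobytes()

    text_start = 58
    # build TEXT with placeholder offsets, then patch once sizes are known
    def build_text(data_start, data_end):
        kv = {
            "$DATATYPE": "F",
            "$MODE": "L",
            "$BYTEORD": "1,2,3,4",
            "$PAR": str(n_par),
            "$TOT": str(n_tot),
            "$NEXTDATA": "0",
            "$BEGINDATA": str(data_start),
            "$ENDDATA": str(data_end),
        }
        for i, name in enumerate(names, start=1):
            kv[f"$P{i}N"] = name
            kv[f"$P{i}B"] = "32"
            kv[f"$P{i}E"] = "0,0"
            kv[f"$P{i}R"] = "262144"
        text = "/" + "/".join(f"{k}/{v}" for k, v in kv.items()) + "/"
        return text.encode("ascii")

    text = build_text(0, 0)
    pad = 256  # room for offset digits to change
    text_len = len(text) + pad
    data_start = text_start + text_len
    data_end = data_start + len(data) - 1
    text = build_text(data_start, data_end)
    text_end = text_start + len(text) - 1  # offset of the final delimiter
    text = text + b" " * (text_len - len(text))

    header = b"FCS3.0    "
    header += f"{text_start:>8d}".encode()
    header += f"{text_end:>8d}".encode()
    header += f"{data_start:>8d}".encode()
    header += f"{data_end:>8d}".encode()
    header += f"{0:>8d}".encode() * 2  # no ANALYSIS segment
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data)


@pytest.fixture
def tiny_events():
    values = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [7.0, 8.0]])
    return gw.EventMatrix(values, ("CD3", "CD4"))


@pytest.fixture
def tiny_partitions():
    labels = np.array([[0, 0, 1, 1], [0, 1, 1, 0]])
    return gw.BasePartitionSet(labels, ("p1", "p2"))


@pytest.fixture
def blob_data():
    """Well-separated 5-cloud dataset with a 4-run k-means ensemble."""
    events, truth = gw.make_blobs(
        gw.BlobSpec(n_events=1500, n_dims=8, n_clusters=5, sd=0.5, seed=7)
    )
    parts = gw.builtin_base_partitions(events, [4, 5, 6, 8], [7, 8, 9, 10])
    return events, truth, parts


@pytest.fixture
def fcs_writer():
    return write_minimal_fcs
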