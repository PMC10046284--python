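import json

import numpy as np
import pytest

from ihcscore import ROI, ROISet, hdab_model


@pytest.fixture(scope="session")
def model():
    return hdab_model()


@pytest.fixture()
def square_roiset():
    """A 10x10 tumor square and a disjoint 10x30 background strip on a 40x40 canvas."""
    tumor = ROI("tumor", [(5, 5), (15, 5), (15, 15), (5, 15)])
    background = ROI("background", [(25, 5), (35, 5), (35, 35), (25, 35)])
    return ROISet(rois=(tumor, background))


def write_geojson(path, features):
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    return path


def polygon_feature(label, ring, close=True):
    ring = [list(map(float, p)) for p in ring]
    if close:
        ring = ring + [ring[0]]
    return {
        "type": "Feature",
        "properties": {"label": label},
        "geometry": {"type": "Polygon", "coordinates": [ring]},
    }
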