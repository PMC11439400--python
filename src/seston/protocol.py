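"""Reference photo-collection protocol metadata.

The study design this package emulates paired each underwater photograph
with a turbidimeter reading in FNU, drawing images from natural habitats
and from two lab mesocosms (an opaque 20 L bucket and a 100 L
recirculating aquarium), with a 4.2 cm quadrant Secchi disk in frame for
a fixed fraction of photos at either 12 or 23 cm from the camera, and
colored-ink tints added in 0.01 mL/L increments. The counts below
describe that reference collection; the simulator's defaults are chosen
to emulate these conditions.
"""

from __future__ import annotations

#: Image counts of the reference collection, by source stratum.
REFERENCE_COLLECTION = {
    "field": {
        "lotic": 298,
        "lentic": 30,
        "brackish": 87,
        "marine": 25,
    },
    "lab": {
        "bucket": 114,
        "aquarium": 121,
    },
}

#: Fraction of reference photos that included the Secchi disk.
SECCHI_FRACTION = 0.38

#: Secchi disk geometry of the reference protocol.
SECCHI_DIAMETER_CM = 4.2
SECCHI_DISTANCES_CM = (12.0, 23.0)

#: Ink tint increment used in the mesocosm protocol (mL/L).
TINT_INCREMENT_ML_PER_L = 0.01

#: Instrument range covered by the collection (FNU).
FNU_RANGE = (0.0, 55.0)


def field_total() -> int:
    """Total field images across habitat strata."""
    return sum(REFERENCE_COLLECTION["field"].values())


def lab_total() -> int:
    """Total lab-mesocosm images across the two systems."""
    return sum(REFERENCE_COLLECTION["lab"].values())


def collection_total() -> int:
    """Total images in the reference collection."""
    return field_total() + lab_total()
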