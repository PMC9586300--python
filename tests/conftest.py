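import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)


def make_presence_matrix(rows, days, dendrite_ids=None, mouse_ids=None, group="g",
                         segment_length_um=80.0, reappearance_events=None):
    """Hand-built PresenceMatrix from a list of binary row vectors."""
    from spinetrack.dynamics import PresenceMatrix

    rows = [np.asarray(r, dtype=np.int8) for r in rows]
    n = len(rows)
    ids = [f"s{i:03d}" for i in range(n)]
    presence = pd.DataFrame(rows, index=ids, columns=list(days))
    cohort = [days[int(np.argmax(r))] for r in rows]
    meta = pd.DataFrame(
        {
            "dendrite_id": dendrite_ids or ["d0"] * n,
            "mouse_id": mouse_ids or ["m0"] * n,
            "group": group,
            "cohort_day": cohort,
            "reappearance_events": reappearance_events or [0] * n,
            "segment_length_um": segment_length_um,
        },
        index=ids,
    )
    return PresenceMatrix(presence, meta)


@pytest.fixture
def single_spine_scene():
    """Noiseless 60-um dendrite with one 2.0-um spine."""
    from spinetrack.synthetic import (
        DendriteGeometry,
        ImagingParams,
        SpineTimeline,
        render_stack,
    )

    geom = DendriteGeometry("d0", "m0", "g", 60.0)
    tl = SpineTimeline(
        spine_id="s1",
        dendrite_id="d0",
        mouse_id="m0",
        group="g",
        session_days=(11,),
        presence=np.array([1], dtype=np.int8),
        position=(32.0, geom.y_center_um + 2.0, geom.z_center_um),
        base_x_um=32.0,
        side=1,
        length_um=2.0,
        is_baseline=True,
    )
    stack = render_stack([tl], geom, 11, ImagingParams(noise=False), jitter_um=(0, 0, 0))
    return geom, tl, stack


def make_scene(lengths_sides_x, segment_um=60.0, noise=False, jitter=(0, 0, 0), rng=None):
    """Render a dendrite with explicitly placed spines.

    ``lengths_sides_x``: list of (length_um, side, x_um) triples.
    """
    from spinetrack.synthetic import (
        DendriteGeometry,
        ImagingParams,
        SpineTimeline,
        render_stack,
    )

    geom = DendriteGeometry("d0", "m0", "g", segment_um)
    tls = []
    for i, (L, side, x) in enumerate(lengths_sides_x):
        tls.append(
            SpineTimeline(
                spine_id=f"s{i}",
                dendrite_id="d0",
                mouse_id="m0",
                group="g",
                session_days=(11,),
                presence=np.array([1], dtype=np.int8),
                position=(x, geom.y_center_um + side * L, geom.z_center_um),
                base_x_um=x,
                side=side,
                length_um=L,
                is_baseline=True,
            )
        )
    im = ImagingParams(noise=noise)
    stack = render_stack(tls, geom, 11, im, rng=rng or np.random.default_rng(0), jitter_um=jitter)
    return geom, tls, stack
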