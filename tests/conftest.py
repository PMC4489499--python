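"""Shared fixtures: bundled scripted sessions and seeded random sessions."""

from __future__ import annotations

import numpy as np
import pytest

from atelier import PageGeometry, SessionEvent, SessionRecord, StudioConfig
from atelier.synth import bundled_fixtures, fixture_suite, random_session


@pytest.fixture(scope="session")
def fixtures():
    """Named fixture sessions with ground truths."""
    return bundled_fixtures()


@pytest.fixture(scope="session")
def suite():
    """Bundled + 16 seeded random scripted sessions (20 total)."""
    return fixture_suite()


@pytest.fixture(scope="session")
def random_sessions():
    """100 seeded random generator sessions with ground truths."""
    return [random_session(seed=50_000 + k) for k in range(100)]


@pytest.fixture
def geometry():
    return PageGeometry(width=20.0, height=20.0)


@pytest.fixture
def config():
    return StudioConfig()


def make_record(events, geometry=None, config=None, **kwargs):
    """Build a validated record from (t, kind, payload) shorthand tuples."""
    geometry = geometry or PageGeometry(width=20.0, height=20.0)
    config = config or StudioConfig()
    evs = [SessionEvent(**e) if isinstance(e, dict) else e for e in events]
    return SessionRecord(geometry=geometry, config=config,
                         events=tuple(evs), **kwargs)


def simple_stroke_events(t0=1.0, t1=2.0, xy0=(1.0, 1.0), xy1=(3.0, 1.0),
                         pressure=0.5, n=3):
    """pen_down .. pen_move .. pen_up along a straight segment."""
    ts = np.linspace(t0, t1, n)
    xs = np.linspace(xy0[0], xy1[0], n)
    ys = np.linspace(xy0[1], xy1[1], n)
    kinds = ["pen_down"] + ["pen_move"] * (n - 2) + ["pen_up"]
    return [dict(t=float(t), kind=k, x=float(x), y=float(y), pressure=pressure)
            for t, k, x, y in zip(ts, kinds, xs, ys)]
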