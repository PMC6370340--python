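import numpy as np
import pytest

from helifret import FretTrace, KineticParams, ReactionConditions


@pytest.fixture(scope="session")
def params():
    return KineticParams()


@pytest.fixture(scope="session")
def saturating():
    return ReactionConditions(atp=1000.0)


def trace_from_fret(E, frame_interval=0.1, injection_frame=20,
                    total=1000.0, background=100.0, released_frame=None,
                    pre_level=0.95):
    """Build a noiseless trace showing FRET profile ``E`` after injection.

    Frames before injection sit at ``pre_level``; frames at and after
    ``released_frame`` (index into the post-injection profile) contain
    only background.
    """
    E = np.asarray(E, dtype=float)
    full = np.concatenate([np.full(injection_frame, pre_level), E])
    if released_frame is not None and injection_frame + released_frame >= len(full):
        pad = injection_frame + released_frame - len(full) + 30
        full = np.concatenate([full, np.full(pad, full[-1])])
    occupied = np.ones(len(full), dtype=bool)
    if released_frame is not None:
        occupied[injection_frame + released_frame:] = False
    acceptor = np.where(occupied, total * full, 0.0) + background
    donor = np.where(occupied, total * (1.0 - full), 0.0) + background
    return FretTrace(frame_interval=frame_interval,
                     injection_frame=injection_frame,
                     donor=donor, acceptor=acceptor,
                     released_frame=(injection_frame + released_frame
                                     if released_frame is not None else None),
                     meta={"background": background})
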