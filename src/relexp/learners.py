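"""Registry of the four learner-contract implementations."""

from __future__ import annotations

from .datamodel import Learner
from .dirac import DIRACLearner
from .ktsp import KTSPLearner
from .tsp import TSPLearner
from .tst import TSTLearner

LEARNERS: dict[str, Learner] = {
    "tsp": TSPLearner(),
    "ktsp": KTSPLearner(),
    "tst": TSTLearner(),
    "dirac": DIRACLearner(),
}


def get_learner(name: str) -> Learner:
    try:
        return LEARNERS[name]
    except KeyError:
        raise KeyError(
            f"unknown algorithm {name!r}; choose from {sorted(LEARNERS)}"
        ) from None
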