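"""Named random substreams derived from one master seed.

Each consumer (object sampling, population noise, weight initialization, ...)
gets its own `numpy.random.Generator`, so adding or removing draws in one
consumer never perturbs the others.
"""
from __future__ import annotations

import numpy as np


class RngStreams:
    _NAMES = ("objects", "parietal_noise", "som_init", "som_noise",
              "premotor_init", "premotor_noise", "misc")

    def __init__(self, seed: int):
        self.seed = int(seed)
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(len(self._NAMES))
        self._streams = {name: np.random.default_rng(child)
                         for name, child in zip(self._NAMES, children)}

    def __getattr__(self, name: str) -> np.random.Generator:
        try:
            return self.__dict__["_streams"][name]
        except KeyError:
            raise AttributeError(name) from None

    def state(self) -> dict:
        return {name: gen.bit_generator.state
                for name, gen in self._streams.items()}

    def set_state(self, state: dict) -> None:
        for name, st in state.items():
            self._streams[name].bit_generator.state = st
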