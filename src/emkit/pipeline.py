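"""Processor concatenation without intermediate files.

A :class:`PipeProc` holds an ordered list of processors and applies them
left to right; the empty pipe is the identity.  Intermediates live only in
memory and a failure at any step propagates annotated with the step index,
leaving no partial result.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Tuple

from .dtypes import Image
from .errors import EmkitError, PipelineError
from .processors import Processor


class PipeProc(Processor):
    name = "pipe"

    def __init__(self, steps: Optional[Iterable[Processor]] = None) -> None:
        super().__init__()
        self._steps: List[Processor] = []
        for p in steps or ():
            self.add_processor(p)

    @property
    def steps(self) -> Tuple[Processor, ...]:
        return tuple(self._steps)

    def add_processor(self, p: Processor) -> "PipeProc":
        if not isinstance(p, Processor):
            raise EmkitError(f"not a Processor: {p!r}")
        self._steps.append(p)
        return self

    def __len__(self) -> int:
        return len(self._steps)

    def process(self, img: Image) -> Image:
        current = img.copy()
        for k, p in enumerate(self._steps):
            try:
                current = p.process(current)
            except Exception as e:
                raise PipelineError(f"step {k} ({p.name}): {e}") from e
        return current
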