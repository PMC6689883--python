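"""Engine configuration.

The two thresholds that shape the search are fixed by the method itself:
unmatched fragments are only merged back into a neighbor when they have fewer
than 8 heavy atoms (small fragments are the ones likely to be pieces of a
monomer), and candidate bonds sitting in rings smaller than 6 atoms are never
cut in the first pass (azoles excepted); such small rings are revisited by the
generic-cycle combinatorics of the secondary pass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from pathlib import Path


@dataclass(frozen=True)
class EngineConfig:
    max_inner_retry_atoms: int = 8  # exclusive bound on retryable fragment size
    min_cycle_size: int = 6  # ring bonds in smaller cycles are not primary cuts
    discovery_mode: bool = False
    max_combinations: int = 10000  # hard safety cap; exceeding it is an error

    @classmethod
    def from_json(cls, path: str | Path) -> "EngineConfig":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
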