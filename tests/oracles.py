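"""Independent oracles for the event counter.

The regex oracle re-derives the dual-threshold counting semantics from the
event signature itself, on symbol strings over the alphabet
``l`` (<= low threshold), ``m`` (between thresholds), ``h`` (>= high
threshold):

* ``at_dip`` events are non-overlapping matches of "an arming 'h', then the
  first run of at least min_dwell consecutive 'l'";
* ``full_cycle`` events additionally require a subsequent 'h', which also
  serves as the next event's arming frame (zero-width lookahead).

This shares no code with the state machine in gqkinetics.kinetics.
"""

import re
from functools import lru_cache


@lru_cache(maxsize=None)
def _patterns(min_dwell: int):
    at_dip = re.compile(rf"h.*?l{{{min_dwell}}}")
    full_cycle = re.compile(rf"h.*?l{{{min_dwell}}}.*?(?=h)")
    return at_dip, full_cycle


def count_events_regex(symbols: str, min_dwell: int, count_mode: str) -> int:
    at_dip, full_cycle = _patterns(min_dwell)
    pat = at_dip if count_mode == "at_dip" else full_cycle
    return len(pat.findall(symbols))
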