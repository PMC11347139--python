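#!/usr/bin/env python
"""Summarize the completed run: per-stage counters, the transcriptional
context distribution ({1, 2, 3, >=4} bins), and the per-gene m6A table.
Writes results/run/report.txt.
"""

from common import RUN_DIR

from btarch.pipeline import report


def main() -> None:
    summary = report(RUN_DIR)
    print((RUN_DIR / "report.txt").read_text())


if __name__ == "__main__":
    main()
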