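"""Shared helpers for the numbered analysis drivers."""

from pathlib import Path

RESULTS = Path(__file__).resolve().parent.parent / "results"


def results_dir(sub: str = "") -> Path:
    d = RESULTS / sub if sub else RESULTS
    d.mkdir(parents=True, exist_ok=True)
    return d


def say(*parts) -> None:
    print("[analysis]", *parts, flush=True)
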