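"""Regenerate the shipped XPDL fixture files from the programmatic builders.

Run from the repository root:  python scripts/build_fixtures.py
"""

from pathlib import Path

from labflow.fixtures import FIXTURE_BUILDERS
from labflow.xpdl_io import serialize_xpdl


def main() -> None:
    out_dir = Path(__file__).resolve().parent.parent / "fixtures"
    out_dir.mkdir(exist_ok=True)
    for name, builder in FIXTURE_BUILDERS.items():
        path = out_dir / f"{name}.xpdl"
        path.write_bytes(serialize_xpdl(builder()))
        print(f"wrote {path}")


if __name__ == "__main__":
    main()
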