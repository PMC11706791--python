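"""Shared paths and lazy data generation for the analysis scripts."""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

RESULTS = ROOT / "results"
DATA = RESULTS / "synthetic"
SEED = 20_26


def ensure_data():
    """Generate the shared synthetic dataset if it is not present."""
    if not (DATA / "truth.json").exists():
        import importlib.util

        spec_path = Path(__file__).parent / "01_simulate.py"
        spec = importlib.util.spec_from_file_location("simulate", spec_path)
        mod = importlib.util.module_from_spec(spec)
        spec.loader.exec_module(mod)
        mod.main()
    return DATA
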