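import sys
from pathlib import Path

from hypothesis import settings

# Let test modules import the local oracle helper regardless of rootdir.
sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")
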