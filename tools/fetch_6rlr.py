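#!/usr/bin/env python
"""Download the deposited CD9 EC2 coordinates (PDB 6rlr) for use with the
superposition tools.  Network access is deliberately kept out of the
library and test suite; run this once by hand if you want to reproduce
the chain A->B / C->D superpositions on the deposited model:

    python tools/fetch_6rlr.py
    twinstack superpose --file 6rlr.cif --moving A --fixed B
    twinstack superpose --file 6rlr.cif --moving C --fixed D
"""

import sys
import urllib.request

URL = "https://files.rcsb.org/download/6RLR.cif"


def main(dest: str = "6rlr.cif") -> None:
    print(f"fetching {URL} -> {dest}")
    urllib.request.urlretrieve(URL, dest)
    print("done")


if __name__ == "__main__":
    main(*sys.argv[1:])
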