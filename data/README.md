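# data

Place the public reference structure here as `3CHY.pdb` (plain-text PDB,
RCSB entry 3CHY) to enable the native-structure acceptance checks:

```sh
curl -o data/3CHY.pdb https://files.rcsb.org/download/3CHY.pdb
```

The file could not be vendored because the build environment had no
network route to the RCSB.
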