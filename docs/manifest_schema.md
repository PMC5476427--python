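# Run-manifest JSON schema

Every pipeline output directory carries a `manifest.json` tying it to its
exact inputs; re-running from the manifest's config reproduces stochastic
outputs bit-identically.

| field        | type            | meaning                                          |
|--------------|-----------------|--------------------------------------------------|
| `scenario`   | string          | scenario name (`wildtype`, `ablation`, ...)      |
| `config`     | object          | full `ScenarioConfig` snapshot (all parameters)  |
| `seeds`      | array[int]      | every RNG seed used by the run                   |
| `version`    | string          | otoquant version that produced the outputs       |
| `thresholds` | object          | analysis thresholds applied (a.u.), by name      |
| `inputs`     | array[string]   | paths of files read                              |
| `outputs`    | array[string]   | paths of files written                           |
| `created`    | string (ISO 8601, UTC) | creation timestamp                        |

Written/read by `otoquant.io_cli.RunManifest`.
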