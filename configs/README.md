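# Scale definitions

Editable YAML definitions of the two instruments (items, response
range, reverse-keyed items, subscale layout).  `fcri.yaml` uses the
package's documented default dimension layout (8/9/4/6/3/3/9 items;
item 13 reverse-keyed); adapt it if your FCRI version assigns items
differently, then load it with `ScaleDefinition.from_yaml(path)`.
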