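{"formatVersion":1,"pathwayId":"FIG1","entities":[{"id":"P1","entityType":"protein","displayName":"Protein 1"},{"id":"P2","entityType":"protein","displayName":"Protein 2"},{"id":"P3","entityType":"protein","displayName":"Protein 3"},{"id":"P4","entityType":"protein","displayName":"Protein 4"},{"id":"SM1","entityType":"chemical","displayName":"Small molecule 1"},{"id":"SM2","entityType":"chemical","displayName":"Small molecule 2"},{"id":"C1","entityType":"complex","displayName":"Complex 1","children":["P1","P2"]},{"id":"C2","entityType":"complex","displayName":"Complex 2","children":["P3","P4","SM1","SM2"]},{"id":"C3","entityType":"complex","displayName":"Complex 3","children":["C1","C2"]}],"reactions":[{"id":"R1","inputs":["P1","P2"],"outputs":["C1"]},{"id":"R2","inputs":["C1","C2"],"outputs":["C3"]}]}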