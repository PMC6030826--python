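{"formatVersion":1,"pathwayId":"FIG1","canvas":{"x":0,"y":0,"width":420,"height":260},"compartments":[{"id":"cytosol","displayName":"cytosol","bbox":{"x":5,"y":5,"width":410,"height":250},"containedGlyphIds":["P1","P2","C1","C2","C3"]}],"nodes":[{"id":"P1","renderClass":"protein","displayName":"Protein 1","bbox":{"x":20,"y":30,"width":60,"height":36}},{"id":"P2","renderClass":"protein","displayName":"Protein 2","bbox":{"x":20,"y":130,"width":60,"height":36}},{"id":"C1","renderClass":"complex","displayName":"Complex 1","bbox":{"x":170,"y":80,"width":60,"height":36}},{"id":"C2","renderClass":"complex","displayName":"Complex 2","bbox":{"x":170,"y":180,"width":60,"height":36}},{"id":"C3","renderClass":"complex","displayName":"Complex 3","bbox":{"x":330,"y":130,"width":60,"height":36}}],"edges":[{"id":"R1","segments":[{"x1":80,"y1":48,"x2":125,"y2":98},{"x1":80,"y1":148,"x2":125,"y2":98},{"x1":125,"y1":98,"x2":170,"y2":98}],"reactionShape":{"x":125,"y":98},"connectors":[{"role":"input","glyphId":"P1"},{"role":"input","glyphId":"P2"},{"role":"output","glyphId":"C1"}]},{"id":"R2","segments":[{"x1":230,"y1":98,"x2":280,"y2":148},{"x1":230,"y1":198,"x2":280,"y2":148},{"x1":280,"y1":148,"x2":330,"y2":148}],"reactionShape":{"x":280,"y":148},"connectors":[{"role":"input","glyphId":"C1"},{"role":"input","glyphId":"C2"},{"role":"output","glyphId":"C3"}]}]}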