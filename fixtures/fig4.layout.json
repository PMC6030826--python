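{"formatVersion":1,"pathwayId":"FIG4","canvas":{"x":0,"y":0,"width":100,"height":100},"nodes":[{"id":"P1","renderClass":"protein","displayName":"P1","bbox":{"x":10,"y":10,"width":0,"height":0}},{"id":"P2","renderClass":"protein","displayName":"P2","bbox":{"x":30,"y":20,"width":0,"height":0}},{"id":"SM1","renderClass":"chemical","displayName":"SM1","bbox":{"x":70,"y":10,"width":0,"height":0}},{"id":"SM2","renderClass":"chemical","displayName":"SM2","bbox":{"x":90,"y":30,"width":0,"height":0}},{"id":"P3","renderClass":"protein","displayName":"P3","bbox":{"x":5,"y":55,"width":0,"height":0}},{"id":"P4","renderClass":"protein","displayName":"P4","bbox":{"x":15,"y":65,"width":0,"height":0}},{"id":"C1","renderClass":"complex","displayName":"C1","bbox":{"x":20,"y":70,"width":0,"height":0}},{"id":"C2","renderClass":"complex","displayName":"C2","bbox":{"x":70,"y":70,"width":0,"height":0}},{"id":"R1","renderClass":"other","displayName":"R1","bbox":{"x":90,"y":90,"width":0,"height":0}}],"edges":[]}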