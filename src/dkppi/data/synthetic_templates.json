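{
  "comment": "Sentence templates for the synthetic corpus generator. Slots: {P1}/{P2} protein mentions, {KV} 3rd-person verb form of the keyword, {KV0} base verb form, {KVP} plural verb form, {KN} noun form, {N1} noise word. 'cue' templates carry a negation cue between the anchors and are used to surface negative labels of non-dominant instances. Every template's tree leaves align 1:1 with its word tokens.",
  "templates": [
    {"position": "infix", "cue": false,
     "tokens": ["{P1}", "{KV}", "{P2}"],
     "tree": "(S (NP (NN {P1})) (VP (VBZ {KV}) (NP (NN {P2}))))"},
    {"position": "infix", "cue": false,
     "tokens": ["The", "{N1}", "{P1}", "{KV}", "{P2}"],
     "tree": "(S (NP (DT The) (NN {N1}) (NN {P1})) (VP (VBZ {KV}) (NP (NN {P2}))))"},
    {"position": "infix", "cue": false,
     "tokens": ["{P1}", "{KV}", "with", "{P2}"],
     "tree": "(S (NP (NN {P1})) (VP (VBZ {KV}) (PP (IN with) (NP (NN {P2})))))"},
    {"position": "infix", "cue": false,
     "tokens": ["{P1}", "{KV}", "the", "{N1}", "of", "{P2}"],
     "tree": "(S (NP (NN {P1})) (VP (VBZ {KV}) (NP (NP (DT the) (NN {N1})) (PP (IN of) (NP (NN {P2}))))))"},
    {"position": "infix", "cue": false,
     "tokens": ["{P1}", ",", "a", "{N1}", ",", "{KV}", "{P2}"],
     "tree": "(S (NP (NP (NN {P1})) (NP (DT a) (NN {N1}))) (VP (VBZ {KV}) (NP (NN {P2}))))"},
    {"position": "infix", "cue": true,
     "tokens": ["{P1}", "does", "not", "{KV0}", "{P2}"],
     "tree": "(S (NP (NN {P1})) (VP (VBZ does) (RB not) (VP (VB {KV0}) (NP (NN {P2})))))"},
    {"position": "infix", "cue": true,
     "tokens": ["{P1}", "fails", "to", "{KV0}", "{P2}"],
     "tree": "(S (NP (NN {P1})) (VP (VBZ fails) (S (VP (TO to) (VP (VB {KV0}) (NP (NN {P2})))))))"},
    {"position": "infix", "cue": true,
     "tokens": ["{P1}", "cannot", "{KV0}", "{P2}"],
     "tree": "(S (NP (NN {P1})) (VP (MD cannot) (VP (VB {KV0}) (NP (NN {P2})))))"},

    {"position": "prefix", "cue": false,
     "tokens": ["{KN}", "of", "{P1}", "with", "{P2}"],
     "tree": "(NP (NP (NN {KN})) (PP (IN of) (NP (NP (NN {P1})) (PP (IN with) (NP (NN {P2}))))))"},
    {"position": "prefix", "cue": false,
     "tokens": ["{KN}", "between", "{P1}", "and", "{P2}"],
     "tree": "(NP (NP (NN {KN})) (PP (IN between) (NP (NP (NN {P1})) (CC and) (NP (NN {P2})))))"},
    {"position": "prefix", "cue": false,
     "tokens": ["the", "{KN}", "of", "{P1}", "and", "{P2}", "was", "{N1}"],
     "tree": "(S (NP (NP (DT the) (NN {KN})) (PP (IN of) (NP (NP (NN {P1})) (CC and) (NP (NN {P2}))))) (VP (VBD was) (ADJP (JJ {N1}))))"},
    {"position": "prefix", "cue": true,
     "tokens": ["{KN}", "of", "{P1}", "but", "not", "{P2}"],
     "tree": "(NP (NP (NN {KN})) (PP (IN of) (NP (NP (NN {P1})) (CC but) (RB not) (NP (NN {P2})))))"},
    {"position": "prefix", "cue": true,
     "tokens": ["{KN}", "of", "{P1}", "without", "{P2}"],
     "tree": "(NP (NP (NN {KN})) (PP (IN of) (NP (NP (NN {P1})) (PP (IN without) (NP (NN {P2}))))))"},

    {"position": "postfix", "cue": false,
     "tokens": ["{P1}", "and", "{P2}", "{KVP}"],
     "tree": "(S (NP (NP (NN {P1})) (CC and) (NP (NN {P2}))) (VP (VBP {KVP})))"},
    {"position": "postfix", "cue": false,
     "tokens": ["{P1}", "{P2}", "{KN}"],
     "tree": "(NP (NN {P1}) (NN {P2}) (NN {KN}))"},
    {"position": "postfix", "cue": false,
     "tokens": ["the", "{P1}", "/", "{P2}", "{KN}", "was", "{N1}"],
     "tree": "(S (NP (DT the) (NN {P1}) (NN {P2}) (NN {KN})) (VP (VBD was) (ADJP (JJ {N1}))))"},
    {"position": "postfix", "cue": true,
     "tokens": ["{P1}", "and", "{P2}", "never", "{KVP}"],
     "tree": "(S (NP (NP (NN {P1})) (CC and) (NP (NN {P2}))) (VP (ADVP (RB never)) (VBP {KVP})))"},
    {"position": "postfix", "cue": true,
     "tokens": ["{P1}", "and", "{P2}", "do", "not", "{KV0}"],
     "tree": "(S (NP (NP (NN {P1})) (CC and) (NP (NN {P2}))) (VP (VBP do) (RB not) (VP (VB {KV0}))))"}
  ]
}
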