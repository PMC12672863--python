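The kitchen window is open and a light wind moves the curtain. A woman stands at the sink drying a plate while water runs over the edge and pools on the floor beside her shoes. She does not seem to notice the puddle spreading toward the table. Behind her a boy has climbed onto a wooden stool to reach the cookie jar on the top shelf of the cupboard. The stool tips under his weight and he holds the shelf with one hand while passing a cookie down to his sister. The girl reaches up with both hands and laughs, asking him to hurry before their mother turns around. Outside the window there is a garden path, a low hedge, and a neighbour raking leaves into a small pile near the fence.

On the counter sit two cups, a dish of butter, and a loaf of bread that has already been sliced. The woman finishes one plate and picks up another, still looking out at the garden. The tap keeps running. The boy leans farther over, and the lid of the jar slides to one side with a quiet scrape. His sister presses a finger to her lips. The cat sleeps on the mat by the door and does not stir even when the stool creaks again.

In the next room a clock ticks on the mantel above a narrow fireplace. There are photographs on the wall, a small one of a wedding and a larger one of children standing in front of a school gate. A radio murmurs the afternoon news from the corner table. Someone has left a book open on the arm of the chair, its pages lifting slightly each time the draught comes through the hall.

Later in the day the light changes and the garden turns a deeper green. The neighbour has finished with the leaves and carries the basket to the end of the path. A delivery van stops at the gate and the driver checks an address against the number painted on the post. He rings twice, waits, and leaves the parcel leaning against the step. The dog across the road barks at the van until it turns the corner and is gone.

The woman finally turns off the tap and sees the water on the floor. She reaches for a towel, calling to the children without looking at them, and the boy climbs down from the stool with the jar held against his chest. The girl hides the first cookie behind her back. For a moment nobody speaks, and then all three of them laugh at once, and the afternoon goes on the way such afternoons do, with small troubles wiped up and forgotten before supper.

When people describe a picture like this they tend to begin with the figures and then move outward to the objects and the weather. They say the mother is washing dishes, the sink is overflowing, the boy is on the stool, the stool is falling, the girl wants a cookie. Some speakers add little judgements, that the children are naughty or that the mother is distracted, and some list only what they can point to. A careful listener notices how often a speaker pauses, how many times a word is repeated, and whether the sentences carry on from one another or start over again from the beginning.

A transcript of ordinary speech keeps a rough record of these habits. Short words follow one another quickly when the speaker is sure of the scene. When the speaker hesitates the words space themselves out, and simple fillers take the place of the nouns that will not come. One person may name every object on the counter in a single breath, while another circles the same cupboard three times, saying the thing, the thing there, the jar, yes the jar. Both are describing the same drawing, yet the shape of their language is entirely different, and some of that shape survives even when the recording is reduced to plain letters and spaces on a page.

Reading such transcripts one after another, certain patterns begin to repeat. Frequent letters carry most of the weight, the vowels and the common consonants, while rare letters appear only when a particular object forces them in. The spaces between words are the most regular feature of all, arriving at almost every fifth or sixth character in fluent speech and more often when the speech breaks into fragments. A long pause does not show itself directly in the letters, but the short words that surround it leave their mark, and over a whole recording these small marks add up to something measurable.

It is an old observation that every speaker has habits of rhythm as personal as handwriting. Children run their clauses together with and then, and then, and then. Older speakers round their sentences more carefully, or abandon them midway and begin again. Under fatigue or distraction the same person produces shorter runs, plainer words, and more frequent boundaries. None of this requires any understanding of what the words mean; it is visible in the bare sequence of letters, the way the stitching is visible on the back of a piece of embroidery.

The scene in the kitchen ends as it always ends. The towel goes back on its hook, the jar goes back on its shelf a little lighter than before, and the water dries in a pale ring on the floorboards. The neighbour's garden is tidy until the next wind. The parcel waits on the step for someone to notice it. And the description of all this, spoken aloud by one person to another, becomes a line of small letters and spaces that still carries, faintly but surely, the fingerprint of the voice that produced it.
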